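"""Seeded generator of transition-level datasets for every study design.

The generator emulates the experimental designs used to characterize a
multiplexed immuno-MRM panel, emitting Skyline-style transition rows
(peptide, label, replicate, fragment, area, background, retention time plus
sample annotations) together with the ground truth that produced them, so
parameter-recovery tests can close the loop.

Generative model for one measurement (peptide p, replicate within a day):

* expected intensity of a label = response_factor_p x amount, scaled by a
  process effect (lognormal, shared by light and heavy within a replicate —
  the internal standard is spiked before digestion, so sample-processing
  variation cancels in the ratio);
* the peak-area ratio carries multiplicative lognormal errors: a between-day
  effect (sigma_inter, log2 domain) and a within-day replicate effect
  (sigma_intra), applied to the light label;
* the label intensity splits across transitions by fixed per-peptide
  fragment proportions, and every transition receives additive detector
  noise N(0, noise_floor) truncated at zero, plus a small positive
  background;
* an interfered transition receives a co-eluting contaminant (extra area
  and a retention-time offset) in the light label only;
* intensities below the dropout threshold are emitted as missing.

The default configuration reproduces the characterization designs exactly:
8-level heavy dilution series (2000 ... 0.205 fmol) in process triplicate
with blanks; 3 spike levels x 3 replicates x 5 days; endogenous 5
replicates x 8 days (n = 40); stability arms in triplicate; 3 panels x 3
sequential-enrichment positions; and cohorts of 77 tissue / 48 plasma
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .response_curve import CURVE_LEVELS_FMOL

LN2 = math.log(2.0)

TISSUE_SITES = (
    "brain", "breast", "colorectal", "endometrium", "head_and_neck",
    "kidney", "lung_adenocarcinoma", "lung_squamous", "ovarian",
    "pancreas", "sarcoma",
)
PLASMA_GROUPS = ("breast", "colorectal", "ovarian")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the characterization designs."""

    panel_size: int = 43
    n_transitions_per_peptide: int = 3
    designs: tuple[str, ...] = (
        "curve", "repeatability", "endogenous", "stability", "sequential", "cohort",
    )
    matrices: tuple[str, ...] = ("tissue", "plasma")

    heavy_spike_fmol: float = 200.0  # internal standard per sample
    light_spike_fmol: float = 200.0  # light spike in curve/repeatability arms

    curve_levels_fmol: tuple[float, ...] = CURVE_LEVELS_FMOL
    curve_replicates: int = 3
    curve_blanks: int = 3

    repeatability_levels_fmol: dict = field(
        default_factory=lambda: {"low": 20.0, "medium": 200.0, "high": 2000.0}
    )
    repeatability_replicates: int = 3
    repeatability_days: int = 5

    endogenous_replicates: int = 5
    endogenous_days: int = 8

    stability_conditions: tuple[str, ...] = ("autosampler_24h", "freeze_thaw_x2")
    stability_replicates: int = 3

    sequential_panels: tuple[str, ...] = ("IO-1", "IO-2", "IO-3")
    sequential_positions: tuple[int, ...] = (1, 2, 3)
    sequential_replicates: int = 3
    position_effect: float = 1.0  # multiplicative depletion per position; 1 = no carryover

    cohort_tissue_n: int = 77
    cohort_plasma_n: int = 48

    # variance components (log2 domain) and detector noise
    sigma_intra: float = 0.072  # ~5% multiplicative CV within day
    sigma_inter: float = 0.058  # ~4% between-day
    sigma_process: float = 0.25  # shared light/heavy processing effect (cancels in PAR)
    noise_floor: float = 110.0  # additive per-transition sd, intensity counts
    plasma_noise_scale: float = 0.45  # plasma floor relative to tissue

    # per-peptide response factors (counts per fmol), lognormal across the
    # panel; MRM responses span orders of magnitude between peptides
    response_factor_median: float = 2000.0
    response_factor_log2_sd: float = 2.0

    # endogenous abundance distributions (fmol per reference aliquot)
    endogenous_tissue_median_fmol: float = 30.0
    endogenous_tissue_log2_sd: float = 2.2
    endogenous_plasma_median_fmol: float = 0.2
    endogenous_plasma_log2_sd: float = 3.0
    site_shift_log2_sd: float = 0.5
    sample_log2_sd: float = 1.2

    stability_shift_log2_mean: float = -0.045  # ~ -3% median storage loss
    stability_shift_log2_sd: float = 0.05

    interference_rate: float = 0.0  # fraction of (peptide, fragment) pairs contaminated
    dropout_threshold: float = 0.0  # intensities below this are emitted as missing

    seed: int = 0

    def __post_init__(self) -> None:
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.n_transitions_per_peptide < 2:
            raise ValueError("assays require at least 2 transitions per peptide")
        for name, val in (
            ("curve_replicates", self.curve_replicates),
            ("repeatability_replicates", self.repeatability_replicates),
            ("endogenous_replicates", self.endogenous_replicates),
        ):
            if val < 1:
                raise ValueError(f"{name} must be >= 1")
        if min(self.sigma_intra, self.sigma_inter, self.sigma_process) < 0:
            raise ValueError("variance components must be >= 0")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside the data, keyed by seed."""

    seed: int
    peptides: pd.DataFrame  # response factors, fragment proportions, endogenous bases, expected LLOQs
    config: SimulationConfig
    interfered: list[tuple[str, str]] = field(default_factory=list)  # (peptide_id, fragment)


# ---------------------------------------------------------------------------


def _amino_acid_pool() -> str:
    return "ACDEFGHILMNPQSTVWY"  # no K/R internally; appended as terminus


def _make_peptides(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.panel_size
    rows = []
    pool = np.array(list(_amino_acid_pool()))
    for i in range(n):
        length = int(rng.integers(7, 16))
        seq = "".join(rng.choice(pool, size=length - 1)) + str(rng.choice(["K", "R"]))
        gene = f"GENE{i + 1:03d}"
        rf = cfg.response_factor_median * 2.0 ** rng.normal(0.0, cfg.response_factor_log2_sd)
        props = rng.dirichlet(np.full(cfg.n_transitions_per_peptide, 8.0))
        rows.append(
            {
                "peptide_id": f"{gene}_{seq[:4]}",
                "gene_symbol": gene,
                "sequence": seq,
                "response_factor": rf,
                "fragment_proportions": ";".join(f"{p:.6f}" for p in props),
                "rt_min": float(rng.uniform(8.0, 35.0)),
                "endo_tissue_fmol": cfg.endogenous_tissue_median_fmol
                * 2.0 ** rng.normal(0.0, cfg.endogenous_tissue_log2_sd),
                "endo_plasma_fmol": cfg.endogenous_plasma_median_fmol
                * 2.0 ** rng.normal(0.0, cfg.endogenous_plasma_log2_sd),
            }
        )
    return pd.DataFrame(rows)


def _noise_floor(cfg: SimulationConfig, matrix: str) -> float:
    return cfg.noise_floor * (cfg.plasma_noise_scale if matrix == "plasma" else 1.0)


def multiplicative_cv(sigma_log2: float) -> float:
    """Fractional CV of a lognormal with the given sd in log2 units."""
    s = sigma_log2 * LN2
    return math.sqrt(math.exp(s * s) - 1.0)


def predicted_par_cv(
    level_fmol: float,
    response_factor: float,
    sigma_intra: float,
    noise_floor: float,
    n_transitions: int,
    other_label_fmol: float,
) -> float:
    """Predicted fractional CV of the PAR at a curve level.

    Combines the multiplicative within-day CV with the additive detector
    noise on each label's summed intensity (sd = noise_floor * sqrt(k) over
    k transitions, relative to mean = response_factor * amount).
    """
    cv_mult = multiplicative_cv(sigma_intra)
    add_var = 0.0
    for amount in (level_fmol, other_label_fmol):
        if amount > 0:
            add_var += (noise_floor * math.sqrt(n_transitions) / (response_factor * amount)) ** 2
    return math.sqrt(cv_mult**2 + add_var)


def expected_lloq(
    truth: SimulationTruth, peptide_id: str, matrix: str = "tissue", cv_limit: float = 0.20
) -> float:
    """Smallest designed level whose predicted PAR CV is below the limit."""
    cfg = truth.config
    row = truth.peptides.set_index("peptide_id").loc[peptide_id]
    floor = _noise_floor(cfg, matrix)
    for level in sorted(cfg.curve_levels_fmol):
        cv = predicted_par_cv(
            level,
            float(row["response_factor"]),
            cfg.sigma_intra,
            floor,
            cfg.n_transitions_per_peptide,
            cfg.light_spike_fmol,
        )
        if cv < cv_limit:
            return level
    return math.nan


# ---------------------------------------------------------------------------


class _Emitter:
    """Accumulates transition rows for one simulation run."""

    def __init__(self, cfg: SimulationConfig, peptides: pd.DataFrame, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.rows: list[dict] = []
        self.peptides = peptides
        self.props = {
            r.peptide_id: np.array([float(x) for x in r.fragment_proportions.split(";")])
            for r in peptides.itertuples(index=False)
        }
        self.rts = {r.peptide_id: r.rt_min for r in peptides.itertuples(index=False)}
        self.rf = {r.peptide_id: r.response_factor for r in peptides.itertuples(index=False)}
        self.interfered: set[tuple[str, str]] = set()
        if cfg.interference_rate > 0:
            for pid in peptides["peptide_id"]:
                for t in range(cfg.n_transitions_per_peptide):
                    if rng.random() < cfg.interference_rate:
                        self.interfered.add((pid, f"y{t + 3}"))

    def day_effect(self) -> float:
        return 2.0 ** self.rng.normal(0.0, self.cfg.sigma_inter)

    def emit_measurement(
        self,
        peptide_id: str,
        replicate_id: str,
        light_fmol: float,
        heavy_fmol: float,
        matrix: str,
        day_effect: float = 1.0,
        ratio_scale: float = 1.0,
        **annotations,
    ) -> None:
        cfg, rng = self.cfg, self.rng
        rf = self.rf[peptide_id]
        props = self.props[peptide_id]
        floor = _noise_floor(cfg, matrix)
        process = 2.0 ** rng.normal(0.0, cfg.sigma_process)
        rep_effect = 2.0 ** rng.normal(0.0, cfg.sigma_intra)
        light_expected = rf * light_fmol * process * day_effect * rep_effect * ratio_scale
        heavy_expected = rf * heavy_fmol * process
        rt0 = self.rts[peptide_id] + rng.normal(0.0, 0.02)
        for label, expected in (("light", light_expected), ("heavy", heavy_expected)):
            for t in range(cfg.n_transitions_per_peptide):
                frag = f"y{t + 3}"
                area = expected * props[t] + rng.normal(0.0, floor)
                rt = rt0
                if label == "light" and (peptide_id, frag) in self.interfered:
                    area += 8.0 * floor + 0.05 * light_expected
                    rt = rt0 + 0.5
                area = max(area, 0.0)
                if cfg.dropout_threshold > 0 and area < cfg.dropout_threshold:
                    area = math.nan
                self.rows.append(
                    {
                        "peptide_id": peptide_id,
                        "label": label,
                        "replicate_id": replicate_id,
                        "fragment_name": frag,
                        "area": area,
                        "background": abs(rng.normal(0.0, 0.1 * floor)) + 0.05 * floor,
                        "retention_time": rt,
                        "matrix": matrix,
                        **annotations,
                    }
                )

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        if self.cfg.dropout_threshold > 0:
            df = df[df["area"].notna()].reset_index(drop=True)
        return df


def _simulate_curve(em: _Emitter, matrix: str) -> None:
    cfg = em.cfg
    for pep in em.peptides["peptide_id"]:
        for level in cfg.curve_levels_fmol:
            for rep in range(1, cfg.curve_replicates + 1):
                em.emit_measurement(
                    pep,
                    f"curve_{matrix}_{level:g}_{rep}",
                    light_fmol=cfg.light_spike_fmol,
                    heavy_fmol=level,
                    matrix=matrix,
                    design="curve",
                    spike_fmol=level,
                    day=1,
                )
        for rep in range(1, cfg.curve_blanks + 1):
            em.emit_measurement(
                pep,
                f"curve_{matrix}_blank_{rep}",
                light_fmol=cfg.light_spike_fmol,
                heavy_fmol=0.0,
                matrix=matrix,
                design="curve",
                spike_fmol=0.0,
                day=1,
            )


def _simulate_repeatability(em: _Emitter, matrix: str) -> None:
    cfg = em.cfg
    for level_name, level in cfg.repeatability_levels_fmol.items():
        for day in range(1, cfg.repeatability_days + 1):
            day_eff = {pep: em.day_effect() for pep in em.peptides["peptide_id"]}
            for rep in range(1, cfg.repeatability_replicates + 1):
                for pep in em.peptides["peptide_id"]:
                    em.emit_measurement(
                        pep,
                        f"rep_{matrix}_{level_name}_d{day}_r{rep}",
                        light_fmol=cfg.light_spike_fmol,
                        heavy_fmol=level,
                        matrix=matrix,
                        day_effect=day_eff[pep],
                        design="repeatability",
                        spike_level=level_name,
                        heavy_spike_fmol=level,
                        day=day,
                    )


def _simulate_endogenous(em: _Emitter, matrix: str) -> None:
    cfg = em.cfg
    endo_col = "endo_tissue_fmol" if matrix == "tissue" else "endo_plasma_fmol"
    endo = dict(zip(em.peptides["peptide_id"], em.peptides[endo_col]))
    for day in range(1, cfg.endogenous_days + 1):
        day_eff = {pep: em.day_effect() for pep in em.peptides["peptide_id"]}
        for rep in range(1, cfg.endogenous_replicates + 1):
            for pep in em.peptides["peptide_id"]:
                em.emit_measurement(
                    pep,
                    f"endo_{matrix}_d{day}_r{rep}",
                    light_fmol=endo[pep],
                    heavy_fmol=cfg.heavy_spike_fmol,
                    matrix=matrix,
                    day_effect=day_eff[pep],
                    design="endogenous",
                    spike_level="endogenous",
                    heavy_spike_fmol=cfg.heavy_spike_fmol,
                    day=day,
                )


def _simulate_stability(em: _Emitter, matrix: str) -> None:
    cfg = em.cfg
    shift = {
        (pep, cond): 2.0
        ** em.rng.normal(cfg.stability_shift_log2_mean, cfg.stability_shift_log2_sd)
        for pep in em.peptides["peptide_id"]
        for cond in cfg.stability_conditions
    }
    for cond in ("fresh",) + cfg.stability_conditions:
        for rep in range(1, cfg.stability_replicates + 1):
            for pep in em.peptides["peptide_id"]:
                em.emit_measurement(
                    pep,
                    f"stab_{matrix}_{cond}_r{rep}",
                    light_fmol=cfg.light_spike_fmol,
                    heavy_fmol=cfg.repeatability_levels_fmol["medium"],
                    matrix=matrix,
                    ratio_scale=shift.get((pep, cond), 1.0),
                    design="stability",
                    condition=cond,
                    heavy_spike_fmol=cfg.repeatability_levels_fmol["medium"],
                    day=1,
                )


def _simulate_sequential(em: _Emitter) -> None:
    cfg = em.cfg
    endo = dict(zip(em.peptides["peptide_id"], em.peptides["endo_tissue_fmol"]))
    for panel in cfg.sequential_panels:
        for position in cfg.sequential_positions:
            depletion = cfg.position_effect ** (position - 1)
            for rep in range(1, cfg.sequential_replicates + 1):
                for pep in em.peptides["peptide_id"]:
                    em.emit_measurement(
                        pep,
                        f"seq_{panel}_p{position}_r{rep}",
                        light_fmol=endo[pep] * depletion,
                        heavy_fmol=cfg.heavy_spike_fmol * depletion,
                        matrix="cell",
                        design="sequential",
                        panel=panel,
                        position=position,
                        heavy_spike_fmol=cfg.heavy_spike_fmol,
                        day=1,
                    )


def _simulate_cohort(em: _Emitter, matrix: str, truth_rows: list[dict]) -> None:
    cfg, rng = em.cfg, em.rng
    endo_col = "endo_tissue_fmol" if matrix == "tissue" else "endo_plasma_fmol"
    base = dict(zip(em.peptides["peptide_id"], em.peptides[endo_col]))
    if matrix == "tissue":
        n, groups = cfg.cohort_tissue_n, TISSUE_SITES
    else:
        n, groups = cfg.cohort_plasma_n, PLASMA_GROUPS
    sites = [groups[i % len(groups)] for i in range(n)]
    site_shift = {
        (pep, site): rng.normal(0.0, cfg.site_shift_log2_sd)
        for pep in em.peptides["peptide_id"]
        for site in groups
    }
    for i, site in enumerate(sites, start=1):
        sample = f"{matrix}_{i:03d}"
        for pep in em.peptides["peptide_id"]:
            amount = base[pep] * 2.0 ** (
                site_shift[(pep, site)] + rng.normal(0.0, cfg.sample_log2_sd)
            )
            truth_rows.append(
                {"peptide_id": pep, "sample_id": sample, "site": site, "matrix": matrix,
                 "true_fmol": amount}
            )
            em.emit_measurement(
                pep,
                f"cohort_{sample}",
                light_fmol=amount,
                heavy_fmol=cfg.heavy_spike_fmol,
                matrix=matrix,
                design="cohort",
                sample_id=sample,
                site=site,
                heavy_spike_fmol=cfg.heavy_spike_fmol,
                day=1,
            )


def simulate_panel(config: SimulationConfig | None = None) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate every requested design; returns (transition table, truth).

    Deterministic under a fixed config (including seed): the same call
    yields byte-identical output.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    peptides = _make_peptides(cfg, rng)
    em = _Emitter(cfg, peptides, rng)
    cohort_truth: list[dict] = []

    for design in cfg.designs:
        if design == "curve":
            for matrix in cfg.matrices:
                _simulate_curve(em, matrix)
        elif design == "repeatability":
            for matrix in cfg.matrices:
                _simulate_repeatability(em, matrix)
        elif design == "endogenous":
            for matrix in cfg.matrices:
                _simulate_endogenous(em, matrix)
        elif design == "stability":
            for matrix in cfg.matrices:
                _simulate_stability(em, matrix)
        elif design == "sequential":
            _simulate_sequential(em)
        elif design == "cohort":
            for matrix in cfg.matrices:
                _simulate_cohort(em, matrix, cohort_truth)
        else:
            raise ValueError(f"unknown design {design!r}")

    truth = SimulationTruth(
        seed=cfg.seed,
        peptides=peptides,
        config=cfg,
        interfered=sorted(em.interfered),
    )
    for matrix in cfg.matrices:
        truth.peptides[f"expected_lloq_{matrix}"] = [
            expected_lloq(truth, pep, matrix) for pep in truth.peptides["peptide_id"]
        ]
    truth.cohort = pd.DataFrame(cohort_truth)  # type: ignore[attr-defined]
    return em.frame(), truth
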