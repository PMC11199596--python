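"""End-to-end orchestration: raw transition report -> characterization bundle.

Runs the stages in dependency order — quantification, response curves (LLOQs
first, since every later stage filters on them), repeatability, stability,
sequential enrichment, cohort detection and minimum-input extrapolation —
and assembles a per-peptide x matrix characterization table plus panel-level
median summaries, with a JSON run manifest (config hash, seed, toggles) so
a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .detection_input import (
    detection_histogram,
    minimum_input_table,
    predicted_detected_at_inputs,
)
from .precision_stability import classify_validation, compute_precision, compute_stability
from .quant_core import (
    HEAVY_OVER_LIGHT,
    LIGHT_OVER_HEAVY,
    filter_by_lloq,
    inferred_amount_fmol,
    summarize_measurements,
)
from .response_curve import characterize_curves
from .sequential_enrichment import correlation_table, summarize_position

ALL_STAGES = ("curves", "precision", "stability", "sequential", "detection")


@dataclass
class RunManifest:
    seed: int | None = None
    config: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ALL_STAGES
    package_version: str = __version__
    config_hash: str = ""

    def finalize(self) -> "RunManifest":
        payload = json.dumps(
            {"config": self.config, "stages": list(self.stages), "seed": self.seed},
            sort_keys=True,
            default=str,
        )
        self.config_hash = hashlib.sha256(payload.encode()).hexdigest()[:16]
        return self


def _median(series: pd.Series) -> float:
    vals = series.dropna()
    return float(vals.median()) if len(vals) else math.nan


def run_full_characterization(
    transitions: pd.DataFrame,
    stages: Sequence[str] = ALL_STAGES,
    seed: int | None = None,
    config: Mapping[str, object] | None = None,
) -> dict:
    """Execute the characterization pipeline on a tidy transition table.

    The table must carry a ``design`` annotation naming the arm each row
    belongs to (curve / repeatability / endogenous / stability / sequential /
    cohort). Returns a dict of stage tables plus ``characterization`` (one
    row per peptide x matrix), ``medians`` (panel-level figures of merit)
    and ``manifest``. Stages whose design arm is absent raise with the arm's
    name unless the stage is not requested.
    """
    if "design" not in transitions.columns:
        raise ValueError("transition table lacks the 'design' annotation")
    stages = tuple(stages)
    present = set(transitions["design"].unique())
    need = {
        "curves": "curve",
        "precision": "repeatability",
        "stability": "stability",
        "sequential": "sequential",
        "detection": "cohort",
    }
    for stage in stages:
        if need[stage] not in present:
            raise ValueError(
                f"stage {stage!r} requires the {need[stage]!r} design arm, which is absent"
            )

    out: dict = {}
    lloq_table = pd.DataFrame(columns=["peptide_id", "matrix", "lloq_fmol"])

    if "curves" in stages:
        curve_meas = summarize_measurements(
            transitions[transitions["design"] == "curve"], orientation=HEAVY_OVER_LIGHT
        )
        out["curve_results"] = characterize_curves(curve_meas)
        lloq_table = out["curve_results"][["peptide_id", "matrix", "lloq_fmol"]].dropna()
    out["lloq_table"] = lloq_table

    if "precision" in stages:
        rep = summarize_measurements(
            transitions[transitions["design"] == "repeatability"], orientation=LIGHT_OVER_HEAVY
        )
        prec = compute_precision(rep)
        if "endogenous" in present:
            endo = summarize_measurements(
                transitions[transitions["design"] == "endogenous"], orientation=LIGHT_OVER_HEAVY
            )
            if len(lloq_table):
                endo = endo.assign(amount_fmol=inferred_amount_fmol(endo))
                endo = filter_by_lloq(endo, lloq_table)
            prec = pd.concat([prec, compute_precision(endo)], ignore_index=True)
        out["precision"] = prec
        out["validation_calls"] = classify_validation(prec)

    if "stability" in stages:
        stab = summarize_measurements(
            transitions[transitions["design"] == "stability"], orientation=LIGHT_OVER_HEAVY
        )
        out["stability"] = compute_stability(stab)

    if "sequential" in stages:
        seq = summarize_measurements(
            transitions[transitions["design"] == "sequential"], orientation=LIGHT_OVER_HEAVY
        )
        seq = seq.assign(amount_fmol=inferred_amount_fmol(seq))
        # the sequential arm runs in cell lysate; LLOQs are matrix-specific,
        # so gate on the tissue LLOQ as the closest characterized matrix
        seq_lloq = lloq_table[lloq_table["matrix"] == "tissue"][["peptide_id", "lloq_fmol"]]
        summaries = summarize_position(seq, seq_lloq if len(seq_lloq) else None)
        tables = []
        panels = summaries["panel"].unique() if "panel" in summaries.columns else [None]
        for panel in panels:
            sub = summaries if panel is None else summaries[summaries["panel"] == panel]
            tab = correlation_table(sub)
            tab.insert(0, "panel", panel)
            tables.append(tab)
        out["sequential_summaries"] = summaries
        out["sequential_correlations"] = pd.concat(tables, ignore_index=True)

    if "detection" in stages:
        cohort = summarize_measurements(
            transitions[transitions["design"] == "cohort"], orientation=LIGHT_OVER_HEAVY
        )
        cohort = cohort.assign(amount_fmol=inferred_amount_fmol(cohort))
        detection_profiles, histograms, min_inputs = [], {}, []
        for matrix, sub in cohort.groupby("matrix"):
            prof, hist = detection_histogram(sub, lloq_table, cohort=str(matrix))
            detection_profiles.append(prof)
            histograms[str(matrix)] = hist
            if matrix == "tissue":
                mi = minimum_input_table(sub, lloq_table)
                min_inputs.append(mi)
        out["detection_profiles"] = pd.concat(detection_profiles, ignore_index=True)
        out["detection_histograms"] = histograms
        if min_inputs:
            out["minimum_input"] = pd.concat(min_inputs, ignore_index=True)
            out["predicted_detected"] = predicted_detected_at_inputs(out["minimum_input"])

    out["characterization"] = build_characterization_table(out)
    out["medians"] = panel_medians(out)
    out["manifest"] = RunManifest(
        seed=seed, config=dict(config or {}), stages=stages
    ).finalize()
    return out


def build_characterization_table(results: Mapping[str, object]) -> pd.DataFrame:
    """Merge stage outputs into one row per peptide x matrix."""
    base = None
    if "curve_results" in results:
        base = pd.DataFrame(results["curve_results"]).drop(columns=["reason"], errors="ignore")
    if "precision" in results:
        prec = pd.DataFrame(results["precision"])
        wide = prec.pivot_table(
            index=["peptide_id", "matrix"],
            columns="level",
            values=["intra_cv_percent", "inter_cv_percent"],
            aggfunc="first",
        )
        wide.columns = [f"{a}_{b}" for a, b in wide.columns]
        wide = wide.reset_index()
        base = wide if base is None else base.merge(wide, on=["peptide_id", "matrix"], how="outer")
    if "stability" in results:
        stab = pd.DataFrame(results["stability"])
        if len(stab):
            sw = stab.pivot_table(
                index=["peptide_id", "matrix"], columns="condition",
                values="percent_difference", aggfunc="first",
            )
            sw.columns = [f"stability_pct_{c}" for c in sw.columns]
            sw = sw.reset_index()
            base = sw if base is None else base.merge(sw, on=["peptide_id", "matrix"], how="outer")
    if "validation_calls" in results:
        calls = pd.DataFrame(results["validation_calls"])
        if len(calls):
            base = base.merge(
                calls.rename(columns={"status": "validation_status", "reasons": "validation_reasons"}),
                on=["peptide_id", "matrix"],
                how="outer",
            )
    if base is None:
        return pd.DataFrame()
    return base.sort_values(["peptide_id", "matrix"], kind="stable").reset_index(drop=True)


def panel_medians(results: Mapping[str, object]) -> pd.DataFrame:
    """Panel-level medians — the figures of merit reported for a panel.

    Peptides flagged unquantifiable (no LLOQ) are excluded from curve-based
    medians, mirroring the above-LLOQ framing of the characterization.
    """
    rows = []

    def add(metric: str, matrix: str, value: float, n: int) -> None:
        if not math.isnan(value):
            rows.append({"metric": metric, "matrix": matrix, "value": value, "n": n})

    if "curve_results" in results:
        curves = pd.DataFrame(results["curve_results"])
        for matrix, sub in curves.groupby("matrix"):
            ok = sub[sub["lloq_fmol"].notna()]
            add("median_lloq_fmol", matrix, _median(ok["lloq_fmol"]), len(ok))
            add("median_dynamic_range_log10", matrix, _median(ok["dynamic_range_log10"]), len(ok))
            add("median_slope", matrix, _median(ok["slope"]), len(ok))
            add("median_r_squared", matrix, _median(ok["r_squared"]), len(ok))
    if "precision" in results:
        prec = pd.DataFrame(results["precision"])
        for (matrix, level), sub in prec.groupby(["matrix", "level"]):
            add(f"median_intra_cv_{level}", matrix, _median(sub["intra_cv_percent"]), len(sub))
            add(f"median_inter_cv_{level}", matrix, _median(sub["inter_cv_percent"]), len(sub))
    if "stability" in results:
        stab = pd.DataFrame(results["stability"])
        for (matrix, cond), sub in stab.groupby(["matrix", "condition"]):
            add(f"median_stability_pct_{cond}", matrix, _median(sub["percent_difference"]), len(sub))
    if "sequential_correlations" in results:
        corr = pd.DataFrame(results["sequential_correlations"])
        ok = corr["r"].dropna()
        if len(ok):
            rows.append({"metric": "sequential_min_r", "matrix": "cell", "value": float(ok.min()), "n": len(ok)})
            rows.append({"metric": "sequential_max_r", "matrix": "cell", "value": float(ok.max()), "n": len(ok)})
    return pd.DataFrame(rows)


def write_bundle(results: Mapping[str, object], out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write every stage table as CSV plus the JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            if path.exists() and not overwrite:
                raise FileExistsError(path)
            obj.to_csv(path, index=False, float_format="%.6g")
        elif isinstance(obj, dict) and name == "detection_histograms":
            for matrix, hist in obj.items():
                hist.rename("n_peptides").to_csv(out_dir / f"detection_histogram_{matrix}.csv")
    manifest = results.get("manifest")
    if manifest is not None:
        (out_dir / "manifest.json").write_text(
            json.dumps(asdict(manifest), indent=2, default=str)
        )
    return out_dir
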