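"""Transition-level records -> per-replicate peptide measurements.

The quantitative readout of a stable-isotope-dilution MRM assay is the peak
area ratio (PAR) between the endogenous ("light") peptide and its spiked
heavy-labeled internal standard. This module performs the four steps that
turn integrated transition areas into that readout:

1. interference screening — a transition is only trusted when the light and
   heavy peptides agree in retention time and in relative fragment-ion
   proportions (a co-eluting contaminant breaks both);
2. transition summation — total intensity per peptide/label/replicate is the
   sum of (peak area + background) over the clean transitions;
3. ratio formation — light/heavy (or heavy/light, for response curves where
   the spiked standard varies) with log2 transform for downstream statistics;
4. LLOQ filtering — measurements are kept only when the inferred analyte
   amount is strictly above the lower limit of quantification.

Absent signal propagates as missing, never as zero: zeros would corrupt CV
and regression estimates downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

LIGHT_OVER_HEAVY = "light_over_heavy"
HEAVY_OVER_LIGHT = "heavy_over_light"

#: Default agreement tolerances for interference screening. The criterion —
#: matching retention times and relative transition areas between labels — is
#: fixed; the numeric thresholds are configurable and recorded in run
#: metadata.
DEFAULT_RT_TOLERANCE_MIN = 0.2
DEFAULT_PROPORTION_TOLERANCE = 0.20

MIN_CLEAN_TRANSITIONS = 2  # an assay needs >=2 interference-free transitions


@dataclass(frozen=True)
class InterferenceFlag:
    peptide_id: str
    replicate_id: str
    fragment_name: str
    rt_delta: float
    proportion_delta: float
    verdict: Literal["clean", "interfered"]


def total_intensity(areas: Sequence[float], backgrounds: Sequence[float] | None = None) -> float:
    """Summed intensity over the used transitions: sum(area + background).

    Returns NaN (missing), not zero, for empty input.
    """
    areas = np.asarray(list(areas), dtype=float)
    if areas.size == 0:
        return math.nan
    if backgrounds is None:
        backgrounds = np.zeros_like(areas)
    else:
        backgrounds = np.asarray(list(backgrounds), dtype=float)
        if backgrounds.shape != areas.shape:
            raise ValueError("areas and backgrounds must have equal length")
    return float(np.sum(areas + backgrounds))


def peak_area_ratio(
    light_total: float, heavy_total: float, orientation: str = LIGHT_OVER_HEAVY
) -> tuple[float, str | None]:
    """Peak area ratio in the requested orientation.

    Returns ``(par, reason)``; ``par`` is NaN with a reason code when the
    denominator is zero or missing. The two orientations are exact
    reciprocals wherever both are defined.
    """
    if orientation == LIGHT_OVER_HEAVY:
        num, den = light_total, heavy_total
    elif orientation == HEAVY_OVER_LIGHT:
        num, den = heavy_total, light_total
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if den is None or (isinstance(den, float) and math.isnan(den)) or den == 0:
        return math.nan, "zero denominator" if den == 0 else "missing denominator"
    if num is None or (isinstance(num, float) and math.isnan(num)):
        return math.nan, "missing numerator"
    return float(num) / float(den), None


def screen_interference(
    light_records: pd.DataFrame,
    heavy_records: pd.DataFrame,
    rt_tolerance: float = DEFAULT_RT_TOLERANCE_MIN,
    proportion_tolerance: float = DEFAULT_PROPORTION_TOLERANCE,
) -> list[InterferenceFlag]:
    """Flag transitions whose light/heavy pair disagree in RT or proportion.

    Both inputs are transition-table slices for one (peptide, replicate).
    For each fragment shared between labels, ``rt_delta`` is the absolute
    retention-time difference and ``proportion_delta`` the absolute
    difference of within-label fragment area proportions. A fragment is
    ``interfered`` when either exceeds its tolerance. The screen is symmetric
    in the two labels by construction.
    """
    shared = sorted(set(light_records["fragment_name"]) & set(heavy_records["fragment_name"]))
    peptide = str(light_records["peptide_id"].iloc[0]) if len(light_records) else ""
    replicate = str(light_records["replicate_id"].iloc[0]) if len(light_records) else ""
    if not shared:
        return []

    def proportions(df: pd.DataFrame) -> dict[str, float]:
        sub = df[df["fragment_name"].isin(shared)]
        total = float(sub["area"].sum())
        if total <= 0:
            return {f: math.nan for f in shared}
        return {
            str(r.fragment_name): float(r.area) / total
            for r in sub.itertuples(index=False)
        }

    def rts(df: pd.DataFrame) -> dict[str, float]:
        return {
            str(r.fragment_name): float(r.retention_time)
            if r.retention_time is not None and not pd.isna(r.retention_time)
            else math.nan
            for r in df.itertuples(index=False)
        }

    p_light, p_heavy = proportions(light_records), proportions(heavy_records)
    rt_light, rt_heavy = rts(light_records), rts(heavy_records)

    flags = []
    for frag in shared:
        rt_delta = abs(rt_light.get(frag, math.nan) - rt_heavy.get(frag, math.nan))
        prop_delta = abs(p_light.get(frag, math.nan) - p_heavy.get(frag, math.nan))
        interfered = (not math.isnan(rt_delta) and rt_delta > rt_tolerance) or (
            not math.isnan(prop_delta) and prop_delta > proportion_tolerance
        )
        flags.append(
            InterferenceFlag(
                peptide_id=peptide,
                replicate_id=replicate,
                fragment_name=frag,
                rt_delta=rt_delta if not math.isnan(rt_delta) else 0.0,
                proportion_delta=prop_delta if not math.isnan(prop_delta) else 0.0,
                verdict="interfered" if interfered else "clean",
            )
        )
    return flags


def summarize_measurements(
    transitions: pd.DataFrame,
    orientation: str = LIGHT_OVER_HEAVY,
    rt_tolerance: float = DEFAULT_RT_TOLERANCE_MIN,
    proportion_tolerance: float = DEFAULT_PROPORTION_TOLERANCE,
    screen: bool = True,
) -> pd.DataFrame:
    """Collapse a tidy transition table to one row per peptide x replicate.

    Output columns: ``light_total``, ``heavy_total``, ``par``, ``log2_par``,
    ``par_orientation``, ``n_used_transitions``, ``used_transitions``,
    ``excluded_transitions``, ``quantifiable``, ``reason`` plus every
    sample-annotation column, carried through unchanged. The result is
    sorted on (peptide_id, replicate_id) so it does not depend on input row
    order.
    """
    core = {"peptide_id", "label", "replicate_id", "fragment_name", "area", "background", "retention_time"}
    ann_cols = [c for c in transitions.columns if c not in core]
    key = ["peptide_id", "replicate_id"]

    # wide layout: one row per (peptide, replicate, fragment) with the light
    # and heavy quantities side by side; vectorized screening follows the
    # same rules as screen_interference()
    wide = transitions.pivot_table(
        index=key + ["fragment_name"],
        columns="label",
        values=["area", "background", "retention_time"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    for col in ("area_light", "area_heavy", "background_light", "background_heavy",
                "retention_time_light", "retention_time_heavy"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide = wide.reset_index()

    shared = wide["area_light"].notna() & wide["area_heavy"].notna()
    wide["shared"] = shared
    grp = wide[shared].groupby(key)
    for lab in ("light", "heavy"):
        totals = grp[f"area_{lab}"].transform("sum")
        prop = wide.loc[shared, f"area_{lab}"] / totals.where(totals > 0)
        wide.loc[shared, f"prop_{lab}"] = prop
    rt_delta = (wide["retention_time_light"] - wide["retention_time_heavy"]).abs()
    prop_delta = (wide.get("prop_light") - wide.get("prop_heavy")).abs()
    if screen:
        interfered = shared & (
            (rt_delta > rt_tolerance).fillna(False)
            | (prop_delta > proportion_tolerance).fillna(False)
        )
    else:
        interfered = pd.Series(False, index=wide.index)
    wide["clean"] = shared & ~interfered
    wide["interfered"] = interfered

    # per-(peptide, replicate) aggregation, fully vectorized; wide is sorted
    # on (peptide, replicate, fragment), so joined fragment lists are ordered
    wide = wide.sort_values(key + ["fragment_name"], kind="stable")
    pairs = wide[key].drop_duplicates().set_index(key).index
    agg = pd.DataFrame(index=pairs)
    clean = wide[wide["clean"]]
    agg["light_total"] = (clean["area_light"] + clean["background_light"].fillna(0)).groupby(
        [clean[k] for k in key]
    ).sum()
    agg["heavy_total"] = (clean["area_heavy"] + clean["background_heavy"].fillna(0)).groupby(
        [clean[k] for k in key]
    ).sum()
    agg["n_used_transitions"] = clean.groupby(key).size()
    agg["n_used_transitions"] = agg["n_used_transitions"].fillna(0).astype(int)
    agg["any_shared"] = wide.groupby(key)["shared"].any()
    agg["used_transitions"] = clean.groupby(key)["fragment_name"].agg(";".join)
    bad = wide[wide["interfered"] | ~wide["shared"]].copy()
    bad["tag"] = np.where(
        bad["interfered"], bad["fragment_name"] + ":interference",
        bad["fragment_name"] + ":not shared between labels",
    )
    agg["excluded_transitions"] = bad.groupby(key)["tag"].agg(";".join)
    agg[["used_transitions", "excluded_transitions"]] = agg[
        ["used_transitions", "excluded_transitions"]
    ].fillna("")

    unquant = ~agg["any_shared"] | (agg["n_used_transitions"] < MIN_CLEAN_TRANSITIONS)
    agg.loc[unquant, ["light_total", "heavy_total"]] = np.nan
    agg.loc[unquant, "n_used_transitions"] = 0
    agg.loc[unquant, "used_transitions"] = ""
    num, den = (
        (agg["light_total"], agg["heavy_total"])
        if orientation == LIGHT_OVER_HEAVY
        else (agg["heavy_total"], agg["light_total"])
    )
    agg["par"] = (num / den.where(den != 0)).where(~unquant)
    agg["par_orientation"] = orientation
    agg["log2_par"] = np.log2(agg["par"].where(agg["par"] > 0))
    agg["reason"] = np.select(
        [
            ~agg["any_shared"],
            agg["n_used_transitions"] < MIN_CLEAN_TRANSITIONS,
            den.isna(),
            den == 0,
            num.isna(),
        ],
        [
            "no shared fragments between labels",
            f"fewer than {MIN_CLEAN_TRANSITIONS} clean transitions",
            "missing denominator",
            "zero denominator",
            "missing numerator",
        ],
        default=None,
    )
    agg["quantifiable"] = agg["reason"].isna()
    agg["reason"] = agg["reason"].where(agg["reason"].notna(), None)

    out = agg.reset_index()
    if ann_cols:
        annotations = transitions.groupby(key, sort=True)[ann_cols].first().reset_index()
        out = annotations.merge(out, on=key, how="right")
    return out.sort_values(key, kind="stable").reset_index(drop=True)


def inferred_amount_fmol(measurements: pd.DataFrame, heavy_spike_col: str = "heavy_spike_fmol") -> pd.Series:
    """Endogenous analyte amount from the stable-isotope-dilution relation.

    amount = PAR(light/heavy) x spiked heavy amount. The spike amount comes
    from the sample annotations (default 200 fmol per sample in the panel's
    designs) — never hard-coded here.
    """
    if heavy_spike_col not in measurements.columns:
        raise KeyError(f"measurements lack the {heavy_spike_col!r} annotation")
    par = measurements["par"].astype(float)
    if (measurements["par_orientation"] == HEAVY_OVER_LIGHT).any():
        flip = measurements["par_orientation"] == HEAVY_OVER_LIGHT
        par = par.where(~flip, 1.0 / par)
    return par * measurements[heavy_spike_col].astype(float)


def filter_by_lloq(
    measurements: pd.DataFrame,
    lloq_table: pd.DataFrame,
    amount_col: str = "amount_fmol",
) -> pd.DataFrame:
    """Keep measurements whose inferred amount is strictly above the LLOQ.

    ``lloq_table`` must have columns (peptide_id, matrix, lloq_fmol).
    Peptides absent from the table are dropped with a warning (conservative:
    an unknown quantification limit cannot certify a measurement). The
    operation is idempotent and monotone in the threshold.
    """
    import logging

    logger = logging.getLogger("iomrm")
    if amount_col not in measurements.columns:
        measurements = measurements.assign(**{amount_col: inferred_amount_fmol(measurements)})
    key = ["peptide_id"] + (["matrix"] if "matrix" in measurements.columns and "matrix" in lloq_table.columns else [])
    merged = measurements.merge(
        lloq_table[key + ["lloq_fmol"]].drop_duplicates(key), on=key, how="left"
    )
    unknown = merged["lloq_fmol"].isna()
    if unknown.any():
        logger.warning(
            "%d measurements dropped: peptides missing from LLOQ table (%s)",
            int(unknown.sum()),
            sorted(merged.loc[unknown, "peptide_id"].unique())[:5],
        )
    kept = merged[~unknown & (merged[amount_col] > merged["lloq_fmol"])]
    return kept.drop(columns=["lloq_fmol"]).reset_index(drop=True)
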