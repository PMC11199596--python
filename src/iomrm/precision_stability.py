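"""Repeatability (intra/inter-assay CV), stability, and validation calls.

The repeatability design measures each peptide in process triplicate on
five independent days at three heavy-spike levels (20 / 200 / 2000 fmol:
low / medium / high), plus the endogenous analyte in 5 replicates over
8 days (n = 40). Two-level precision decomposition on the untransformed
peak area ratio:

* **intra-assay CV** — the unweighted mean over days of the within-day
  %CV (100 * sd / mean, sample sd);
* **inter-assay CV** — the %CV of the per-day means.

Stability compares the PAR of processed samples stored on the autosampler
for ~24 h at 4 degC, or taken through two freeze-thaw cycles, against a
fresh aliquot, as a percent difference of triplicate means.

A peptide fails validation in a matrix when more than one (level x
intra/inter) condition exceeds the 20% CV threshold; a single exceedance is
a pass with a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CV_THRESHOLD_PCT = 20.0

LEVEL_FMOL = {"low": 20.0, "medium": 200.0, "high": 2000.0}


def _cv_percent(values: Sequence[float]) -> float:
    vals = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if vals.size < 2:
        return math.nan
    if vals.max() == vals.min():  # exact ties: CV is 0, not a rounding residue
        return 0.0
    m = vals.mean()
    if m == 0:
        return math.nan
    return 100.0 * float(vals.std(ddof=1)) / float(m)


def intra_assay_cv(par_by_day: Mapping[object, Sequence[float]]) -> float:
    """Mean over days of the within-day %CV.

    Days with fewer than two usable replicates are skipped (with the skip
    visible as a reduced day count); NaN when no day is usable.
    """
    day_cvs = []
    for _, pars in sorted(par_by_day.items(), key=lambda kv: str(kv[0])):
        cv = _cv_percent(pars)
        if not math.isnan(cv):
            day_cvs.append(cv)
    return float(np.mean(day_cvs)) if day_cvs else math.nan


def inter_assay_cv(par_by_day: Mapping[object, Sequence[float]]) -> float:
    """%CV of the per-day mean PARs; NaN with fewer than two usable days."""
    means = []
    for _, pars in sorted(par_by_day.items(), key=lambda kv: str(kv[0])):
        vals = [p for p in pars if not math.isnan(p)]
        if vals:
            means.append(float(np.mean(vals)))
    if len(means) < 2:
        return math.nan
    return _cv_percent(means)


def stability_percent_difference(
    stored_pars: Sequence[float], fresh_pars: Sequence[float]
) -> float:
    """100 * (mean(stored) - mean(fresh)) / mean(fresh); NaN when fresh mean
    is zero or missing."""
    stored = [p for p in stored_pars if not math.isnan(p)]
    fresh = [p for p in fresh_pars if not math.isnan(p)]
    if not stored or not fresh:
        return math.nan
    mf = float(np.mean(fresh))
    if mf == 0:
        return math.nan
    return 100.0 * (float(np.mean(stored)) - mf) / mf


@dataclass
class PrecisionResult:
    peptide_id: str
    matrix: str
    level: str  # low / medium / high / endogenous
    intra_cv_percent: float
    inter_cv_percent: float
    n_days: int
    n_reps_per_day: int


@dataclass
class ValidationCall:
    peptide_id: str
    matrix: str
    status: str  # pass / pass_with_flag / fail
    reasons: list[str] = field(default_factory=list)


def compute_precision(
    measurements: pd.DataFrame,
    level_col: str = "spike_level",
    day_col: str = "day",
) -> pd.DataFrame:
    """Intra/inter-assay CV per peptide x matrix x level from a tidy table."""
    rows = []
    for (pep, matrix, level), grp in measurements.groupby(
        ["peptide_id", "matrix", level_col], sort=True
    ):
        by_day = {day: list(sub["par"].astype(float)) for day, sub in grp.groupby(day_col)}
        reps = [len(v) for v in by_day.values()]
        rows.append(
            vars(
                PrecisionResult(
                    peptide_id=pep,
                    matrix=matrix,
                    level=str(level),
                    intra_cv_percent=intra_assay_cv(by_day),
                    inter_cv_percent=inter_assay_cv(by_day),
                    n_days=len(by_day),
                    n_reps_per_day=max(reps) if reps else 0,
                )
            )
        )
    return pd.DataFrame(rows)


def compute_stability(
    measurements: pd.DataFrame,
    condition_col: str = "condition",
    fresh_label: str = "fresh",
) -> pd.DataFrame:
    """Percent difference vs fresh per peptide x matrix x storage condition."""
    rows = []
    for (pep, matrix), grp in measurements.groupby(["peptide_id", "matrix"], sort=True):
        fresh = grp.loc[grp[condition_col] == fresh_label, "par"].astype(float).tolist()
        for condition, sub in grp[grp[condition_col] != fresh_label].groupby(condition_col):
            rows.append(
                {
                    "peptide_id": pep,
                    "matrix": matrix,
                    "condition": condition,
                    "percent_difference": stability_percent_difference(
                        sub["par"].astype(float).tolist(), fresh
                    ),
                }
            )
    return pd.DataFrame(rows)


def classify_validation(
    precision_results: pd.DataFrame,
    cv_threshold: float = CV_THRESHOLD_PCT,
    fail_min_exceedances: int = 2,
    spiked_levels: tuple[str, ...] = ("low", "medium", "high"),
) -> pd.DataFrame:
    """Pass/fail call per peptide x matrix from the spiked-level CVs.

    ``fail`` when at least ``fail_min_exceedances`` (level x intra/inter)
    conditions exceed the CV threshold ("multiple sample concentrations
    showing CV > threshold"); exactly one exceedance is ``pass_with_flag``.
    Reasons enumerate every offending condition.
    """
    calls = []
    spiked = precision_results[precision_results["level"].isin(spiked_levels)]
    for (pep, matrix), grp in spiked.groupby(["peptide_id", "matrix"], sort=True):
        reasons = []
        for row in grp.itertuples(index=False):
            for kind in ("intra", "inter"):
                cv = getattr(row, f"{kind}_cv_percent")
                if not math.isnan(cv) and cv > cv_threshold:
                    reasons.append(f"{kind} CV {cv:.1f}% > {cv_threshold:g}% at {row.level}")
        if len(reasons) >= fail_min_exceedances:
            status = "fail"
        elif reasons:
            status = "pass_with_flag"
        else:
            status = "pass"
        calls.append(vars(ValidationCall(pep, matrix, status, reasons)))
    out = pd.DataFrame(calls)
    if len(out):
        out["reasons"] = out["reasons"].map("; ".join)
    return out
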