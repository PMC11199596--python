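"""Response curves: log-log linearity, LLOQ/ULOQ, and dynamic range.

A response curve spikes the heavy internal standard at an 8-point dilution
series (2000, 200, 20, 8, 3.2, 1.28, 0.512, 0.205 fmol) into background
matrix, with the light peptide held constant, in process triplicate plus
blanks. The peak area ratio (heavy/light orientation, since the heavy
amount is the variable) is regressed on the spiked amount in log-log space.

Empirical limits of quantification:

* **LLOQ** — the lowest concentration whose replicate CV is < 20% while the
  linear correlation over all points from it upward stays >= 0.98 (and, in
  the default strict mode, all higher points also keep CV < 20%);
* **ULOQ** — the highest concentration still inside the linear range; when
  the curve is linear to the top of the design, the ULOQ is only a minimum
  estimate;
* **dynamic range** — log10(ULOQ / LLOQ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: The designed heavy-spike dilution series, in fmol.
CURVE_LEVELS_FMOL = (2000.0, 200.0, 20.0, 8.0, 3.2, 1.28, 0.512, 0.205)

CV_THRESHOLD_PCT = 20.0
CORRELATION_THRESHOLD = 0.98


@dataclass
class CurvePoint:
    peptide_id: str
    matrix: str
    spiked_heavy_fmol: float
    pars: list[float]  # heavy/light per process replicate

    @property
    def mean_par(self) -> float:
        vals = [p for p in self.pars if not math.isnan(p)]
        return float(np.mean(vals)) if vals else math.nan

    @property
    def cv_percent(self) -> float:
        vals = [p for p in self.pars if not math.isnan(p)]
        if len(vals) < 2:
            return math.nan
        if max(vals) == min(vals):  # exact ties: CV is 0, not a rounding residue
            return 0.0
        m = float(np.mean(vals))
        if m == 0:
            return math.nan
        return 100.0 * float(np.std(vals, ddof=1)) / m


@dataclass
class ResponseCurveResult:
    peptide_id: str
    matrix: str
    slope: float = math.nan
    intercept: float = math.nan
    r: float = math.nan
    r_squared: float = math.nan
    lloq_fmol: float = math.nan
    uloq_fmol: float = math.nan
    uloq_is_minimum_estimate: bool = False
    dynamic_range_log10: float = math.nan
    lod_fmol: float = math.nan
    n_points_fit: int = 0
    reason: str | None = None


def fit_loglog(
    concentrations: Sequence[float], mean_pars: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS of log2(mean PAR) on log2(spiked fmol).

    Returns (slope, intercept, r, r_squared); NaNs with fewer than 3 usable
    points or non-positive responses.
    """
    x, y = [], []
    for c, p in zip(concentrations, mean_pars):
        if c > 0 and p is not None and not math.isnan(p) and p > 0:
            x.append(math.log2(c))
            y.append(math.log2(p))
    if len(x) < 3:
        return math.nan, math.nan, math.nan, math.nan
    if len(set(x)) < 3:
        return math.nan, math.nan, math.nan, math.nan
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.rvalue**2)


def determine_lloq(
    points: Sequence[CurvePoint],
    cv_threshold: float = CV_THRESHOLD_PCT,
    correlation_threshold: float = CORRELATION_THRESHOLD,
    use_r_squared: bool = False,
    strict_upper_cvs: bool = True,
) -> float:
    """Scan from the lowest concentration up for the first acceptable point.

    A candidate concentration is the LLOQ when (i) its replicate CV is below
    ``cv_threshold``, (ii) the log-log fit over all points at or above it has
    linear correlation >= ``correlation_threshold`` (Pearson r by default,
    r^2 when ``use_r_squared``), and (iii) in strict mode every higher point
    also keeps CV below the threshold ("maintained" precision over the
    region). NaN when no point qualifies.
    """
    pts = sorted(points, key=lambda p: p.spiked_heavy_fmol)
    for i, cand in enumerate(pts):
        upper = pts[i:]
        if math.isnan(cand.cv_percent) or cand.cv_percent >= cv_threshold:
            continue
        if strict_upper_cvs and any(
            (not math.isnan(p.cv_percent)) and p.cv_percent >= cv_threshold for p in upper[1:]
        ):
            continue
        if len(upper) >= 3:
            _, _, r, r2 = fit_loglog(
                [p.spiked_heavy_fmol for p in upper], [p.mean_par for p in upper]
            )
            stat = r2 if use_r_squared else r
            if math.isnan(stat) or stat < correlation_threshold:
                continue
        return cand.spiked_heavy_fmol
    return math.nan


def determine_uloq(
    points: Sequence[CurvePoint],
    lloq: float,
    correlation_threshold: float = CORRELATION_THRESHOLD,
    use_r_squared: bool = True,
    max_studentized_residual: float = 3.0,
) -> tuple[float, bool]:
    """Highest concentration maintained in the linear range above the LLOQ.

    Starting from all points in [LLOQ, max], the top point is dropped while
    the fit including it fails the linearity criterion (R^2 by default) or
    its studentized residual exceeds the bound. ``is_minimum_estimate`` is
    true when the returned ULOQ is the highest designed concentration (the
    curve never left the linear range, so the true ULOQ lies above it).
    """
    if math.isnan(lloq):
        return math.nan, False
    pts = sorted(
        (p for p in points if p.spiked_heavy_fmol >= lloq),
        key=lambda p: p.spiked_heavy_fmol,
    )
    top_design = max(p.spiked_heavy_fmol for p in points)
    while len(pts) >= 3:
        x = [p.spiked_heavy_fmol for p in pts]
        y = [p.mean_par for p in pts]
        slope, intercept, r, r2 = fit_loglog(x, y)
        stat = r2 if use_r_squared else r
        ok = not math.isnan(stat) and stat >= correlation_threshold
        if ok and len(pts) > 3:
            lx = [math.log2(c) for c in x]
            ly = [math.log2(p) if p > 0 else math.nan for p in y]
            resid = np.array(ly) - (slope * np.array(lx) + intercept)
            s = float(np.std(resid, ddof=2))
            if s > 0 and abs(resid[-1]) / s > max_studentized_residual:
                ok = False
        if ok:
            uloq = pts[-1].spiked_heavy_fmol
            return uloq, uloq == top_design
        pts = pts[:-1]
    # fewer than 3 points between LLOQ and candidate: fall back to highest
    if pts:
        uloq = pts[-1].spiked_heavy_fmol
        return uloq, uloq == top_design
    return math.nan, False


def dynamic_range(lloq: float, uloq: float) -> float:
    """Orders of magnitude spanned by the quantifiable range."""
    if math.isnan(lloq) or math.isnan(uloq) or lloq <= 0 or uloq <= 0:
        return math.nan
    return math.log10(uloq / lloq)


def limit_of_detection(blank_pars: Sequence[float]) -> float:
    """Mean blank + 3 sd, in PAR units; diagnostic only, not part of LLOQ."""
    vals = [p for p in blank_pars if not math.isnan(p)]
    if len(vals) < 2:
        return math.nan
    return float(np.mean(vals) + 3.0 * np.std(vals, ddof=1))


def build_curve_points(
    measurements: pd.DataFrame,
    spike_col: str = "spike_fmol",
) -> dict[tuple[str, str], list[CurvePoint]]:
    """Group a measurement table into per-(peptide, matrix) curve points.

    Expects heavy/light PAR orientation and a ``spike_col`` annotation with
    the designed heavy amount (NaN or 0 for blanks, which are kept apart).
    """
    out: dict[tuple[str, str], list[CurvePoint]] = {}
    df = measurements.dropna(subset=[spike_col])
    df = df[df[spike_col] > 0]
    for (pep, matrix, level), grp in df.groupby(["peptide_id", "matrix", spike_col], sort=True):
        out.setdefault((pep, matrix), []).append(
            CurvePoint(
                peptide_id=pep,
                matrix=matrix,
                spiked_heavy_fmol=float(level),
                pars=[float(v) for v in grp["par"]],
            )
        )
    return out


def characterize_curves(
    measurements: pd.DataFrame,
    spike_col: str = "spike_fmol",
    cv_threshold: float = CV_THRESHOLD_PCT,
    correlation_threshold: float = CORRELATION_THRESHOLD,
    lloq_use_r_squared: bool = False,
    strict_upper_cvs: bool = True,
) -> pd.DataFrame:
    """Full response-curve characterization, one row per peptide x matrix."""
    blanks = measurements[
        measurements[spike_col].isna() | (measurements[spike_col] <= 0)
    ]
    results = []
    for (pep, matrix), pts in build_curve_points(measurements, spike_col).items():
        res = ResponseCurveResult(peptide_id=pep, matrix=matrix)
        res.lloq_fmol = determine_lloq(
            pts,
            cv_threshold=cv_threshold,
            correlation_threshold=correlation_threshold,
            use_r_squared=lloq_use_r_squared,
            strict_upper_cvs=strict_upper_cvs,
        )
        if math.isnan(res.lloq_fmol):
            res.reason = "no point satisfies the CV/linearity rule; not quantifiable"
        else:
            res.uloq_fmol, res.uloq_is_minimum_estimate = determine_uloq(
                pts, res.lloq_fmol, correlation_threshold=correlation_threshold
            )
            fit_pts = [
                p
                for p in pts
                if res.lloq_fmol <= p.spiked_heavy_fmol <= res.uloq_fmol
            ]
            res.slope, res.intercept, res.r, res.r_squared = fit_loglog(
                [p.spiked_heavy_fmol for p in fit_pts],
                [p.mean_par for p in fit_pts],
            )
            res.n_points_fit = len(fit_pts)
            res.dynamic_range_log10 = dynamic_range(res.lloq_fmol, res.uloq_fmol)
        bl = blanks[(blanks["peptide_id"] == pep) & (blanks["matrix"] == matrix)]
        if len(bl):
            res.lod_fmol = limit_of_detection([float(v) for v in bl["par"]])
        results.append(res)
    return pd.DataFrame([vars(r) for r in results]).sort_values(
        ["peptide_id", "matrix"], kind="stable"
    ).reset_index(drop=True)
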