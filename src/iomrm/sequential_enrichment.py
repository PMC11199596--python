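"""Sequential multi-panel enrichment concordance.

Several antibody panels can be applied to a single digested sample in
series: each panel's beads capture their analytes from the previous
panel's flow-through. If capture is quantitative and carryover negligible,
a panel should report the same analyte levels whether it ran first, second,
or third. This module checks that by correlating per-peptide triplicate
medians of light area, heavy area, and peak area ratio between enrichment
positions, for analytes above the LLOQ.

Areas span orders of magnitude, so the correlation is computed on log10
medians (Pearson); a multiplicative level shift between positions (partial
depletion) then moves the intercept, not the correlation.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant_core import filter_by_lloq


def summarize_position(
    measurements: pd.DataFrame,
    lloq_table: pd.DataFrame | None = None,
    positions: Sequence[int] = (1, 2, 3),
) -> pd.DataFrame:
    """Per (panel, position, peptide) medians over process replicates.

    Only measurements above the LLOQ contribute when an ``lloq_table`` is
    given; sub-LLOQ peptides drop out of the affected position only, and the
    pairwise correlations below handle the resulting partial overlap.
    Raises when a requested position is entirely absent.
    """
    present = set(int(p) for p in measurements["position"].dropna().unique())
    missing = [p for p in positions if p not in present]
    if missing:
        raise ValueError(f"enrichment position(s) {missing} absent from the measurements")
    df = measurements
    if lloq_table is not None:
        df = filter_by_lloq(df, lloq_table)
    group_cols = ["panel", "position", "peptide_id"] if "panel" in df.columns else ["position", "peptide_id"]
    rows = []
    for key, grp in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(group_cols, key))
        rec.update(
            median_light_area=float(grp["light_total"].median()),
            median_heavy_area=float(grp["heavy_total"].median()),
            median_par=float(grp["par"].median()),
            n_replicates=int(len(grp)),
        )
        rows.append(rec)
    return pd.DataFrame(rows)


_QUANTITY_COL = {
    "light": "median_light_area",
    "heavy": "median_heavy_area",
    "par": "median_par",
}


def position_correlation(
    summaries: pd.DataFrame,
    quantity: str,
    pos_a: int,
    pos_b: int,
    log_transform: bool = True,
) -> tuple[float, int]:
    """Pearson r of (log10) medians between two enrichment positions.

    Pairwise-complete over the peptides present (above LLOQ) at both
    positions; NaN with fewer than 3 shared peptides. Symmetric in the two
    positions.
    """
    col = _QUANTITY_COL[quantity]
    a = summaries[summaries["position"] == pos_a].set_index("peptide_id")[col]
    b = summaries[summaries["position"] == pos_b].set_index("peptide_id")[col]
    shared = sorted(set(a.index) & set(b.index))
    xs, ys = [], []
    for pep in shared:
        x, y = float(a[pep]), float(b[pep])
        if math.isnan(x) or math.isnan(y):
            continue
        if log_transform:
            if x <= 0 or y <= 0:
                continue
            x, y = math.log10(x), math.log10(y)
        xs.append(x)
        ys.append(y)
    if len(xs) < 3:
        return math.nan, len(xs)
    if np.std(xs) == 0 or np.std(ys) == 0:
        return math.nan, len(xs)
    r, _ = stats.pearsonr(xs, ys)
    return float(r), len(xs)


def correlation_table(
    summaries: pd.DataFrame,
    positions: Sequence[int] = (1, 2, 3),
    quantities: Sequence[str] = ("light", "heavy", "par"),
    log_transform: bool = True,
) -> pd.DataFrame:
    """All quantity x position-pair correlations (one panel's summaries)."""
    rows = []
    for quantity in quantities:
        for pos_a, pos_b in combinations(positions, 2):
            r, n = position_correlation(summaries, quantity, pos_a, pos_b, log_transform)
            rows.append(
                {"quantity": quantity, "pos_a": pos_a, "pos_b": pos_b, "r": r, "n": n}
            )
    return pd.DataFrame(rows)
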