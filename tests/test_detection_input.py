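"""Detection profiling and minimum-input extrapolation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iomrm import detection_input as di


def _cohort(amounts_by_peptide, n_samples=4):
    rows = []
    for pep, amount in amounts_by_peptide.items():
        for i in range(n_samples):
            rows.append(
                {
                    "peptide_id": pep,
                    "sample_id": f"s{i}",
                    "matrix": "tissue",
                    "amount_fmol": amount,
                }
            )
    return pd.DataFrame(rows)


class TestDetectionHistogram:
    def test_everything_detected_when_far_above_lloq(self):
        lloq = pd.DataFrame(
            {"peptide_id": ["P1", "P2"], "matrix": "tissue", "lloq_fmol": [0.5, 0.5]}
        )
        prof, hist = di.detection_histogram(_cohort({"P1": 5.0, "P2": 5.0}), lloq, "tissue")
        assert (prof["detection_fraction"] == 1.0).all()
        assert hist.to_dict() == {4: 2}

    def test_unknown_peptide_excluded_with_warning(self, caplog):
        lloq = pd.DataFrame({"peptide_id": ["P1"], "matrix": "tissue", "lloq_fmol": [0.5]})
        with caplog.at_level("WARNING", logger="iomrm"):
            prof, _ = di.detection_histogram(_cohort({"P1": 5.0, "P2": 5.0}), lloq, "tissue")
        assert set(prof["peptide_id"]) == {"P1"}
        assert any("no LLOQ" in m for m in caplog.messages)


class TestMinimumInput:
    def test_zero_variance_reduces_to_linear_scaling(self):
        res = di.minimum_input([2.05] * 5, lloq_fmol=0.205)
        assert res.confident_above_lloq
        assert res.min_input_ug == pytest.approx(50.0, rel=1e-12)

    def test_amounts_at_lloq_not_confident(self):
        res = di.minimum_input([0.205] * 5, lloq_fmol=0.205)
        assert not res.confident_above_lloq
        assert math.isnan(res.min_input_ug)

    def test_matches_t_bound_formula_oracle(self):
        rng = np.random.default_rng(17)
        lloq = 0.4
        amounts = lloq * 8.0 * rng.lognormal(0.0, 0.5, size=7)
        res = di.minimum_input(amounts, lloq)
        r = np.log2(amounts / lloq)
        lb = r.mean() - stats.t.ppf(0.95, 6) * r.std(ddof=1) / math.sqrt(7)
        assert res.confident_above_lloq == (lb > 0)
        assert res.min_input_ug == pytest.approx(500.0 / 2**lb, rel=1e-9)

    def test_too_few_samples_is_missing(self):
        res = di.minimum_input([1.0], 0.1)
        assert res.reason is not None and not res.confident_above_lloq

    def test_nonpositive_amounts_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="iomrm"):
            res = di.minimum_input([2.0, 2.0, 0.0, -1.0], 0.1)
        assert res.n == 2
        assert any("non-positive" in m for m in caplog.messages)


class TestPredictedDetected:
    def _table(self, min_inputs):
        return pd.DataFrame(
            {
                "peptide_id": [f"P{i}" for i in range(len(min_inputs))],
                "tissue_site": "breast",
                "confident_above_lloq": True,
                "min_input_ug": min_inputs,
                "ci_low_ug": min_inputs,
                "ci_high_ug": min_inputs,
            }
        )

    def test_hand_counts(self):
        out = di.predicted_detected_at_inputs(self._table([5.0, 40.0, 300.0]))
        assert out.sort_values("input_ug")["n_predicted"].tolist() == [1, 2, 2, 3]

    def test_reference_input_counts_all_confident(self):
        tab = self._table([5.0, 40.0, 300.0])
        out = di.predicted_detected_at_inputs(tab, input_grid_ug=[500.0])
        assert out["n_predicted"].iloc[0] == 3

    def test_counts_monotone_in_input(self):
        rng = np.random.default_rng(2)
        tab = self._table(sorted(rng.uniform(1, 600, size=25)))
        out = di.predicted_detected_at_inputs(tab, input_grid_ug=[5, 20, 80, 320, 640])
        counts = out.sort_values("input_ug")["n_predicted"].tolist()
        assert counts == sorted(counts)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            di.predicted_detected_at_inputs(self._table([5.0]), input_grid_ug=[])


def test_zero_variance_cohort_minimum_input_exact(zero_noise_bundle):
    from iomrm.quant_core import inferred_amount_fmol, summarize_measurements
    from iomrm.response_curve import characterize_curves
    from iomrm.quant_core import HEAVY_OVER_LIGHT

    _, records, truth = zero_noise_bundle
    curve = summarize_measurements(
        records[records["design"] == "curve"], orientation=HEAVY_OVER_LIGHT
    )
    lloq = characterize_curves(curve)[["peptide_id", "matrix", "lloq_fmol"]]
    cohort = summarize_measurements(records[records["design"] == "cohort"])
    cohort = cohort.assign(amount_fmol=inferred_amount_fmol(cohort))
    tissue = cohort[cohort["matrix"] == "tissue"]
    table = di.minimum_input_table(tissue, lloq)
    truth_amounts = truth.peptides.set_index("peptide_id")["endo_tissue_fmol"]
    for row in table.itertuples(index=False):
        amount = truth_amounts[row.peptide_id]
        expected = 500.0 * 0.205 / amount  # LLOQ is the lowest level, noise-free
        if amount > 0.205:
            assert row.confident_above_lloq
            assert row.min_input_ug == pytest.approx(expected, rel=1e-9)
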