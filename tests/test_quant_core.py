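"""Quantification core: summation, ratios, interference, LLOQ filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iomrm import quant_core as qc


class TestTotalIntensity:
    def test_sums_area_plus_background(self):
        assert qc.total_intensity([100, 200], [10, 20]) == 330.0
        assert qc.total_intensity([50], [0]) == 50.0

    def test_empty_is_missing_not_zero(self):
        assert math.isnan(qc.total_intensity([]))

    def test_excluding_flagged_transition_changes_sum(self):
        areas, bgs = [100.0, 200.0, 300.0], [1.0, 2.0, 3.0]
        flagged = 1  # middle transition interfered
        kept = [i for i in range(3) if i != flagged]
        expected = sum(areas[i] + bgs[i] for i in kept)
        assert qc.total_intensity(
            [areas[i] for i in kept], [bgs[i] for i in kept]
        ) == expected


class TestPeakAreaRatio:
    def test_orientations(self):
        assert qc.peak_area_ratio(1000, 500, qc.LIGHT_OVER_HEAVY)[0] == 2.0
        assert qc.peak_area_ratio(1000, 500, qc.HEAVY_OVER_LIGHT)[0] == 0.5

    def test_zero_denominator_is_missing_with_reason(self):
        par, reason = qc.peak_area_ratio(1000, 0, qc.LIGHT_OVER_HEAVY)
        assert math.isnan(par) and reason == "zero denominator"

    @given(
        light=st.floats(1e-6, 1e9, allow_nan=False),
        heavy=st.floats(1e-6, 1e9, allow_nan=False),
    )
    @settings(deadline=None, max_examples=200)
    def test_orientation_product_is_one(self, light, heavy):
        a, _ = qc.peak_area_ratio(light, heavy, qc.LIGHT_OVER_HEAVY)
        b, _ = qc.peak_area_ratio(light, heavy, qc.HEAVY_OVER_LIGHT)
        assert a * b == pytest.approx(1.0, rel=1e-12)


def _label_frame(peptide, replicate, label, fragments, areas, rts):
    return pd.DataFrame(
        {
            "peptide_id": peptide,
            "label": label,
            "replicate_id": replicate,
            "fragment_name": fragments,
            "area": areas,
            "background": 0.0,
            "retention_time": rts,
        }
    )


class TestInterferenceScreen:
    def test_identical_profiles_all_clean(self):
        frags = ["y3", "y4", "y5"]
        light = _label_frame("P", "r1", "light", frags, [50, 30, 20], [10, 10, 10])
        heavy = _label_frame("P", "r1", "heavy", frags, [500, 300, 200], [10, 10, 10])
        flags = qc.screen_interference(light, heavy)
        assert all(f.verdict == "clean" for f in flags)

    def test_distorted_proportion_flags_only_that_fragment(self):
        frags = ["y3", "y4", "y5"]
        light = _label_frame("P", "r1", "light", frags, [70, 15, 15], [10, 10, 10])
        heavy = _label_frame("P", "r1", "heavy", frags, [30, 35, 35], [10, 10, 10])
        flags = {f.fragment_name: f for f in qc.screen_interference(light, heavy)}
        assert flags["y3"].verdict == "interfered"
        assert flags["y3"].proportion_delta == pytest.approx(0.40)
        # the compensating fragments sit exactly at the 0.20 boundary: clean
        assert flags["y4"].verdict == "clean" and flags["y5"].verdict == "clean"

    def test_rt_shift_everywhere_makes_measurement_unquantifiable(self):
        frags = ["y3", "y4"]
        light = _label_frame("P", "r1", "light", frags, [50, 50], [10.5, 10.5])
        heavy = _label_frame("P", "r1", "heavy", frags, [50, 50], [10.0, 10.0])
        flags = qc.screen_interference(light, heavy, rt_tolerance=0.2)
        assert all(f.verdict == "interfered" for f in flags)
        df = pd.concat([light, heavy])
        meas = qc.summarize_measurements(df)
        assert not meas["quantifiable"].iloc[0]
        assert "clean transitions" in meas["reason"].iloc[0]

    def test_screen_is_symmetric_in_labels(self):
        frags = ["y3", "y4", "y5"]
        light = _label_frame("P", "r1", "light", frags, [70, 15, 15], [10, 10, 10.5])
        heavy = _label_frame("P", "r1", "heavy", frags, [30, 35, 35], [10, 10, 10])
        fwd = {f.fragment_name: f.verdict for f in qc.screen_interference(light, heavy)}
        rev = {f.fragment_name: f.verdict for f in qc.screen_interference(heavy, light)}
        assert fwd == rev


class TestSummarize:
    def test_matches_manual_route_on_clean_data(self):
        frags = ["y3", "y4", "y5"]
        light = _label_frame("P", "r1", "light", frags, [50.0, 30.0, 20.0], [10] * 3)
        heavy = _label_frame("P", "r1", "heavy", frags, [500.0, 300.0, 200.0], [10] * 3)
        light["background"] = [1.0, 2.0, 3.0]
        heavy["background"] = [4.0, 5.0, 6.0]
        meas = qc.summarize_measurements(pd.concat([light, heavy]))
        assert meas["light_total"].iloc[0] == pytest.approx(106.0)
        assert meas["heavy_total"].iloc[0] == pytest.approx(1015.0)
        assert meas["par"].iloc[0] == pytest.approx(106.0 / 1015.0, rel=1e-12)

    def test_interfered_fragment_excluded_from_both_labels(self):
        frags = ["y3", "y4", "y5"]
        light = _label_frame("P", "r1", "light", frags, [70.0, 15.0, 15.0], [10] * 3)
        heavy = _label_frame("P", "r1", "heavy", frags, [30.0, 35.0, 35.0], [10] * 3)
        meas = qc.summarize_measurements(pd.concat([light, heavy]))
        assert meas["n_used_transitions"].iloc[0] == 2
        assert meas["light_total"].iloc[0] == pytest.approx(30.0)
        assert meas["heavy_total"].iloc[0] == pytest.approx(70.0)
        assert "y3:interference" in meas["excluded_transitions"].iloc[0]


class TestLloqFilter:
    def _measurements(self, amounts):
        return pd.DataFrame(
            {
                "peptide_id": "P",
                "replicate_id": [f"r{i}" for i in range(len(amounts))],
                "matrix": "tissue",
                "par": np.asarray(amounts) / 200.0,
                "par_orientation": qc.LIGHT_OVER_HEAVY,
                "heavy_spike_fmol": 200.0,
                "amount_fmol": amounts,
            }
        )

    def _lloq(self, value):
        return pd.DataFrame(
            {"peptide_id": ["P"], "matrix": ["tissue"], "lloq_fmol": [value]}
        )

    def test_strictly_above_lloq_retained(self):
        out = qc.filter_by_lloq(self._measurements([0.1, 0.3, 5.0]), self._lloq(0.205))
        assert sorted(out["amount_fmol"]) == [0.3, 5.0]

    def test_zero_lloq_keeps_all_positive(self):
        out = qc.filter_by_lloq(self._measurements([0.1, 0.3, 5.0]), self._lloq(0.0))
        assert len(out) == 3

    def test_monotone_and_idempotent(self):
        meas = self._measurements([0.1, 0.3, 1.5, 5.0, 50.0])
        lo = qc.filter_by_lloq(meas, self._lloq(0.205))
        hi = qc.filter_by_lloq(meas, self._lloq(3.2))
        assert set(hi["amount_fmol"]) <= set(lo["amount_fmol"])
        again = qc.filter_by_lloq(lo, self._lloq(0.205))
        pd.testing.assert_frame_equal(lo, again)

    def test_unknown_peptide_dropped_with_warning(self, caplog):
        meas = self._measurements([5.0])
        other = pd.DataFrame(
            {"peptide_id": ["Q"], "matrix": ["tissue"], "lloq_fmol": [0.2]}
        )
        with caplog.at_level("WARNING", logger="iomrm"):
            out = qc.filter_by_lloq(meas, other)
        assert len(out) == 0
        assert any("missing from LLOQ" in m for m in caplog.messages)


def test_amount_inference_uses_spike_annotation():
    meas = pd.DataFrame(
        {
            "peptide_id": ["P", "P"],
            "par": [0.5, 2.0],
            "par_orientation": [qc.LIGHT_OVER_HEAVY, qc.HEAVY_OVER_LIGHT],
            "heavy_spike_fmol": [200.0, 200.0],
        }
    )
    amounts = qc.inferred_amount_fmol(meas)
    assert amounts.tolist() == [100.0, 100.0]
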