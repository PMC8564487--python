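"""ELISpot, tumor-volume, cytotoxicity, IHC immunoscore and summary arithmetic."""

import itertools
import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepscaffold import (
    ElispotRecord,
    IhcCounts,
    NotEvaluable,
    TumorMeasurement,
    cross_reactivity_percent,
    cytotoxicity_percent,
    elispot_report,
    elispot_sfc,
    group_summary,
    immunoscore_ratio,
    necrosis_percent,
    tumor_volume,
)

counts = st.floats(min_value=0, max_value=1e4, allow_nan=False)


class TestElispotSfc:
    @pytest.mark.parametrize(
        "duplicates, neg, expected",
        [((50, 60), 10, 45.0), ((5, 5), 20, 0.0), ((0, 0), 0, 0.0)],
    )
    def test_duplicate_mean_minus_background(self, duplicates, neg, expected):
        rec = ElispotRecord("g", "c", duplicates, neg)
        assert elispot_sfc(rec) == expected

    @settings(max_examples=200, derandomize=True)
    @given(counts, counts, counts)
    def test_floor_invariant(self, a, b, neg):
        assert elispot_sfc(ElispotRecord("g", "c", (a, b), neg)) >= 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ElispotRecord("g", "c", (-1, 5), 0)


class TestCrossReactivity:
    def test_self_is_exactly_100(self):
        assert cross_reactivity_percent(45.0, 45.0) == 100.0

    def test_ninety_percent_case(self):
        assert cross_reactivity_percent(81.0, 90.0) == pytest.approx(90.0)

    def test_zero_reference_not_evaluable(self):
        with pytest.raises(NotEvaluable):
            cross_reactivity_percent(10.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0, max_value=1e4, allow_nan=False),
        st.floats(min_value=1e-3, max_value=1e4, allow_nan=False),
        st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
    )
    def test_scale_invariance(self, challenge, self_sfc, scale):
        base = cross_reactivity_percent(challenge, self_sfc)
        rescaled = cross_reactivity_percent(challenge * scale, self_sfc * scale)
        assert rescaled == pytest.approx(base, rel=1e-9)


class TestTumorVolume:
    @pytest.mark.parametrize(
        "A, B, expected", [(10, 8, 320.0), (0, 0, 0.0), (6, 6, 108.0)]
    )
    def test_caliper_formula(self, A, B, expected):
        assert tumor_volume(TumorMeasurement(A, B)) == expected

    def test_sphere_proxy_limit(self):
        d = 7.3
        assert tumor_volume(TumorMeasurement(d, d)) == pytest.approx(d**3 / 2)

    def test_swapped_diameters_corrected(self, caplog):
        m = TumorMeasurement(A=5, B=9)
        assert (m.A, m.B) == (9, 5)

    @settings(max_examples=100, derandomize=True)
    @given(
        st.floats(min_value=0.1, max_value=50, allow_nan=False),
        st.floats(min_value=0.1, max_value=50, allow_nan=False),
        st.floats(min_value=0.01, max_value=5, allow_nan=False),
    )
    def test_monotone_in_both_diameters(self, a, b, delta):
        a, b = max(a, b), min(a, b)
        v = tumor_volume(TumorMeasurement(a, b))
        assert tumor_volume(TumorMeasurement(a + delta, b)) > v
        assert tumor_volume(TumorMeasurement(a + delta, b + delta)) > v

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            TumorMeasurement(-1, 0)


class TestImmunoscore:
    def test_cytotoxic_example(self):
        ratio, label = immunoscore_ratio(IhcCounts("s", "CT", cd3=10, grzb=4, foxp3=2))
        assert ratio == pytest.approx(0.2)
        assert label == "cytotoxic"

    def test_balanced_example(self):
        ratio, label = immunoscore_ratio(IhcCounts("s", "CT", cd3=10, grzb=2, foxp3=2))
        assert ratio == 0.0
        assert label == "balanced"

    def test_immunosuppressive_from_reported_group_means(self):
        # IM means of the strongest group: GrzB 8.4 would be the peri-tumoral
        # value; intra-tumoral CT means give (7.2 - 18.8)/103.1.
        ratio, label = immunoscore_ratio(
            IhcCounts("s", "IM", cd3=103.1, grzb=7.2, foxp3=18.8)
        )
        assert ratio == pytest.approx(-0.112512, abs=1e-6)
        assert label == "immunosuppressive"

    def test_zero_cd3_not_evaluable(self):
        with pytest.raises(NotEvaluable):
            immunoscore_ratio(IhcCounts("s", "CT", cd3=0, grzb=1, foxp3=0))

    def test_sign_rule_exhaustive_grid(self):
        values = [0.0, 1.0, 2.5, 7.0]
        for grzb, foxp3 in itertools.product(values, repeat=2):
            ratio, label = immunoscore_ratio(
                IhcCounts("s", "CT", cd3=10.0, grzb=grzb, foxp3=foxp3)
            )
            if grzb > foxp3:
                assert ratio > 0 and label == "cytotoxic"
            elif grzb < foxp3:
                assert ratio < 0 and label == "immunosuppressive"
            else:
                assert ratio == 0 and label == "balanced"

    def test_marker_above_cd3_warns_not_errors(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pepscaffold.assays"):
            IhcCounts("s", "CT", cd3=1.0, grzb=5.0, foxp3=0.0)
        assert any("exceeds" in rec.message for rec in caplog.records)


class TestNecrosisPercent:
    @pytest.mark.parametrize(
        "necrosis, total, expected", [(25, 100, 25.0), (0, 7, 0.0), (7, 7, 100.0)]
    )
    def test_percentage(self, necrosis, total, expected):
        assert necrosis_percent(necrosis, total) == expected

    @pytest.mark.parametrize("necrosis, total", [(5, 0), (10, 5), (-1, 5)])
    def test_bounds_enforced(self, necrosis, total):
        with pytest.raises(ValueError):
            necrosis_percent(necrosis, total)


class TestCytotoxicity:
    def test_maximal_kill(self):
        assert cytotoxicity_percent(100, 100, 0.0) == 100.0

    def test_background_equals_signal(self):
        assert cytotoxicity_percent(10, 100, 0.1) == 0.0

    def test_spontaneous_correction_arithmetic(self):
        assert cytotoxicity_percent(30, 100, 0.1) == pytest.approx(200 / 9, abs=1e-9)
        assert round(cytotoxicity_percent(30, 100, 0.1), 1) == 22.2

    def test_no_targets_not_evaluable(self):
        with pytest.raises(NotEvaluable):
            cytotoxicity_percent(0, 0)

    def test_floor_at_zero(self):
        assert cytotoxicity_percent(5, 100, 0.5) == 0.0


class TestGroupSummary:
    def test_constant_group(self):
        out = group_summary(
            [{"group": "a", "value": 3.0}] * 3, grouping="group"
        )
        assert out.loc[0, "mean"] == 3.0
        assert out.loc[0, "sem"] == 0.0

    def test_hand_computed_sem(self):
        out = group_summary(
            [{"group": "a", "value": v} for v in (1.0, 2.0, 3.0)], grouping="group"
        )
        assert out.loc[0, "mean"] == 2.0
        assert out.loc[0, "sem"] == pytest.approx(1 / math.sqrt(3), abs=1e-9)

    def test_singleton_group_sem_not_evaluable(self):
        out = group_summary([{"group": "a", "value": 5.0}], grouping="group")
        assert out.loc[0, "mean"] == 5.0
        assert math.isnan(out.loc[0, "sem"])

    def test_purity_same_table_same_report(self):
        table = [{"group": g, "value": v}
                 for g, v in [("a", 1.0), ("b", 2.0), ("a", 3.0)]]
        first, second = group_summary(table, "group"), group_summary(table, "group")
        pd.testing.assert_frame_equal(first, second)


class TestElispotReport:
    def test_self_reference_defines_100(self):
        records = [
            ElispotRecord("E7wt", "E7wt", (95, 105), 10),   # SFC 90
            ElispotRecord("E7wt", "Y4V", (86, 96), 10),     # SFC 81
        ]
        report = elispot_report(records)
        by = report.set_index("challenge")
        assert by.loc["E7wt", "reactivity_pct"] == pytest.approx(100.0)
        assert by.loc["Y4V", "reactivity_pct"] == pytest.approx(90.0)

    def test_missing_self_row_yields_nan(self):
        report = elispot_report([ElispotRecord("g", "other", (10, 10), 0)])
        assert math.isnan(report.loc[0, "reactivity_pct"])
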