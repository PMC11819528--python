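"""Plausibility bounds, Tukey fences and longitudinal consistency."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmamgrowth.cleaning import (
    clean_visits, drop_empty_visits, enforce_longitudinal_consistency,
    flag_implausible_values, flag_zscore_outliers, tukey_fences,
)

from conftest import make_visits


class TestBounds:
    @pytest.mark.parametrize(
        "var, value, blanked",
        [
            ("weight_kg", 3.4, True), ("weight_kg", 3.5, False),
            ("weight_kg", 41.0, True),
            ("muac_mm", 205.0, True), ("muac_mm", 69.0, True),
            ("muac_mm", 200.0, False),
            ("height_cm", 100.0, False), ("height_cm", 59.9, True),
            ("height_cm", 121.0, True),
        ],
    )
    def test_bound_rules(self, var, value, blanked):
        visits = make_visits("X", {var: [value]})
        out, report = flag_implausible_values(visits)
        assert np.isnan(out[var].iloc[0]) == blanked
        assert report.total_flagged == int(blanked)

    def test_empty_visits_dropped(self):
        v1 = make_visits("X", {"weight_kg": [8.0, np.nan], "height_cm": [80.0, np.nan],
                               "muac_mm": [120.0, np.nan]})
        out, n = drop_empty_visits(v1)
        assert n == 1 and len(out) == 1


class TestTukey:
    def test_constant_vector_no_outliers(self):
        assert not flag_zscore_outliers([2.0] * 10).any()

    def test_single_extreme_flagged(self):
        mask = flag_zscore_outliers([0, 0, 0, 0, 0, 0, 0, 100.0])
        assert list(mask) == [False] * 7 + [True]

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            flag_zscore_outliers([np.nan, np.nan])

    @given(st.lists(st.floats(-10, 10), min_size=8, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_mask_mirrors_under_negation(self, xs):
        x = np.array(xs)
        assert (flag_zscore_outliers(x) == flag_zscore_outliers(-x)).all()

    def test_fences_match_numpy_quantiles(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=101)
        lo, hi = tukey_fences(x)
        q1, q3 = np.quantile(x, [0.25, 0.75])
        assert lo == pytest.approx(q1 - 1.5 * (q3 - q1))
        assert hi == pytest.approx(q3 + 1.5 * (q3 - q1))


class TestLongitudinal:
    def test_negative_height_blanks_later(self):
        v = make_visits("X", {"height_cm": [70.0, 69.5]})
        out, report = enforce_longitudinal_consistency(v)
        assert np.isnan(out["height_cm"].iloc[1])
        assert report.by_rule() == {"negative_height": 1}

    def test_weekly_weight_jump_blanks_later(self):
        v = make_visits("X", {"weight_kg": [6.0, 7.7]})
        out, report = enforce_longitudinal_consistency(v)
        assert np.isnan(out["weight_kg"].iloc[1])
        assert report.by_rule() == {"weekly_delta": 1}

    def test_stable_series_untouched(self):
        v = make_visits("X", {"weight_kg": [6.0, 6.4, 6.8],
                              "height_cm": [70.0, 70.5, 71.0],
                              "muac_mm": [115.0, 118.0, 121.0]})
        out, report = enforce_longitudinal_consistency(v)
        assert report.total_flagged == 0
        pd.testing.assert_frame_equal(out, v)

    def test_comparison_skips_missing_and_scales_with_gap(self):
        # visits at weeks 0, 2: gap of 2 weeks doubles the weight limit
        v = make_visits("X", {"weight_kg": [6.0, 8.5]}, weeks=[0, 2])
        out, _ = enforce_longitudinal_consistency(v)
        assert out["weight_kg"].iloc[1] == 8.5   # delta 2.5 < 2 * 1.5
        # gap capped at 4 weeks
        v2 = make_visits("X", {"weight_kg": [6.0, 12.5]}, weeks=[0, 8])
        out2, _ = enforce_longitudinal_consistency(v2)
        assert np.isnan(out2["weight_kg"].iloc[1])  # delta 6.5 > 4 * 1.5

    def test_blanked_value_does_not_become_anchor(self):
        # the 7.7 jump is blanked; 6.1 is then compared against 6.0, not 7.7
        v = make_visits("X", {"weight_kg": [6.0, 7.7, 6.1]})
        out, _ = enforce_longitudinal_consistency(v)
        assert np.isnan(out["weight_kg"].iloc[1])
        assert out["weight_kg"].iloc[2] == 6.1

    def test_unsorted_input_errors(self):
        v = make_visits("X", {"weight_kg": [6.0, 6.1]}, weeks=[1, 0])
        with pytest.raises(ValueError):
            enforce_longitudinal_consistency(v)


class TestFullPass:
    def test_idempotent_on_simulated_cohort(self, reference, small_cohort):
        """A second pass is a fixed point: identical output, no new
        measurement flags, and the identical z-outlier set (the z rule
        blanks derived scores, which are recomputed each pass)."""
        once, r1 = clean_visits(small_cohort.visits, reference)
        twice, r2 = clean_visits(once.drop(columns=["whz", "waz", "haz", "muacz"]),
                                 reference)
        pd.testing.assert_frame_equal(once, twice)
        measurement_rules = {"bounds", "negative_height", "weekly_delta"}
        assert all(rule not in measurement_rules for rule, _ in r2.counts)
        z1 = {(a["child_id"], a["visit_date"], a["variable"])
              for a in r1.audit if a["rule"] == "z_outlier"}
        z2 = {(a["child_id"], a["visit_date"], a["variable"])
              for a in r2.audit if a["rule"] == "z_outlier"}
        assert z1 == z2

    def test_counts_sum_and_zscore_missingness(self, reference, small_cohort):
        cleaned, report = clean_visits(small_cohort.visits, reference)
        assert report.total_flagged == sum(report.by_rule().values())
        assert report.total_flagged == len(report.audit)
        # no silent imputation: z missing wherever an input is missing
        assert cleaned.loc[cleaned["weight_kg"].isna(), ["whz", "waz"]].isna().all().all()
        assert cleaned.loc[cleaned["height_cm"].isna(), ["whz", "haz"]].isna().all().all()
        assert cleaned.loc[cleaned["muac_mm"].isna(), "muacz"].isna().all()
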