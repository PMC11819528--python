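"""Exit-outcome classification and the analysis-set flow."""

import numpy as np
import pandas as pd
import pytest

from cmamgrowth.outcomes import (
    ExitOutcome, FlowCounts, build_analysis_set, classify_all, classify_exit,
)

from conftest import make_visits


def record(label, muac_exit, whz_exit, weeks=16, oedema_adm=False):
    n = weeks + 1
    v = make_visits(
        "X",
        {
            "muac_mm": [110.0] * (n - 1) + [muac_exit],
            "weight_kg": [7.0] * n,
            "oedema": [oedema_adm] + [False] * (n - 1),
        },
    )
    v["whz"] = [-3.0] * (n - 1) + [whz_exit]
    return v


class TestClassifyExit:
    @pytest.mark.parametrize("label", ["recovered", "non_responder"])
    def test_study_labels_pass_through(self, label):
        out = classify_exit(record(label, 110.0, -3.0), label)
        assert out.final_label == label and not out.reclassified

    @pytest.mark.parametrize(
        "label, reason", [("died", "died"), ("medical_transfer", "medical_transfer")]
    )
    def test_terminal_outcomes_excluded(self, label, reason):
        out = classify_exit(record(label, 126.0, -1.0), label)
        assert out.final_label == "excluded" and out.exclusion_reason == reason

    def test_oedema_at_admission_excluded_first(self):
        out = classify_exit(record("recovered", 126.0, -1.0, oedema_adm=True),
                            "recovered")
        assert out.exclusion_reason == "oedema_at_admission"

    def test_unknown_reclassified_recovered(self):
        # one criterion above threshold, no severe criterion remaining
        out = classify_exit(record("unknown", 126.0, -2.5), "unknown")
        assert out.final_label == "recovered" and out.reclassified

    def test_defaulter_reclassified_non_responder(self):
        out = classify_exit(record("defaulter", 118.0, -2.6), "defaulter")
        assert out.final_label == "non_responder" and out.reclassified

    def test_short_stay_excluded(self):
        out = classify_exit(record("defaulter", 126.0, -1.0, weeks=8), "defaulter")
        assert out.exclusion_reason == "short_stay_lt_12wk" and out.los_weeks == 8

    def test_one_criterion_met_other_severe_is_unclassifiable(self):
        # MUAC recovered but WHZ still severely wasted: neither rule applies
        out = classify_exit(record("unknown", 126.0, -3.4), "unknown")
        assert out.exclusion_reason == "unclassifiable"

    def test_missing_exit_anthropometry_unclassifiable(self):
        v = record("unknown", np.nan, np.nan)
        v["muac_mm"] = np.nan
        v["whz"] = np.nan
        v["weight_kg"] = 7.0
        out = classify_exit(v, "unknown")
        assert out.exclusion_reason == "unclassifiable"

    def test_exit_values_from_last_non_missing_visit(self):
        v = record("unknown", np.nan, -2.5)
        v.loc[len(v) - 1, "muac_mm"] = np.nan
        v.loc[len(v) - 2, "muac_mm"] = 126.0
        out = classify_exit(v, "unknown")
        assert out.exit_muac_mm == 126.0 and out.final_label == "recovered"

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ExitOutcome("X", "recovered", "excluded", None, 16, False)
        with pytest.raises(ValueError):
            ExitOutcome("X", "recovered", "recovered", None, 16, True)


class TestHandBuiltFlow:
    """Independent re-application of the full rule set on hand-built records."""

    CASES = [
        # (label, muac_exit, whz_exit, weeks, oedema, expected final)
        ("recovered", 126, -1.5, 6, False, "recovered"),
        ("recovered", 110, -3.0, 16, False, "recovered"),      # pass-through wins
        ("non_responder", 118, -2.5, 16, False, "non_responder"),
        ("died", 126, -1.5, 4, False, "excluded"),
        ("medical_transfer", 118, -2.5, 6, False, "excluded"),
        ("recovered", 126, -1.5, 6, True, "excluded"),          # oedema first
        ("unknown", 126, -2.5, 16, False, "recovered"),
        ("unknown", 124, -1.9, 14, False, "recovered"),         # WHZ criterion
        ("unknown", 124, -2.1, 16, False, "non_responder"),
        ("unknown", 126, -3.4, 16, False, "excluded"),          # contradictory
        ("unknown", 126, -1.5, 8, False, "excluded"),           # short stay
        ("defaulter", 130, -1.0, 13, False, "recovered"),
        ("defaulter", 114, -2.5, 16, False, "non_responder"),   # MUAC still severe but both < cutoffs
        ("defaulter", 118, -2.5, 11, False, "excluded"),
        ("defaulter", 118, -2.5, 12, False, "non_responder"),   # boundary LOS
        ("unknown", 115, -3.0, 16, False, "non_responder"),     # both below cut-offs
        ("recovered", 126, -1.5, 2, False, "recovered"),
        ("non_responder", 110, -3.5, 20, False, "non_responder"),
        ("unknown", 125, -2.9, 16, False, "recovered"),         # MUAC tie at 125
        ("defaulter", 124.9, -2.0, 16, False, "recovered"),     # WHZ tie at -2
    ]

    def build(self):
        visits, labels = [], []
        for i, (label, muac, whz, weeks, oed, _) in enumerate(self.CASES):
            v = record(label, muac, whz, weeks=weeks, oedema_adm=oed)
            v["child_id"] = f"H{i:02d}"
            visits.append(v)
            labels.append((f"H{i:02d}", label))
        return (
            pd.concat(visits, ignore_index=True),
            pd.DataFrame(labels, columns=["child_id", "original_label"]),
        )

    def test_final_labels_match_hand_classification(self):
        visits, labels = self.build()
        out = classify_all(visits, labels).set_index("child_id")
        for i, case in enumerate(self.CASES):
            assert out.loc[f"H{i:02d}", "final_label"] == case[-1], case

    def test_flow_counts_conserve(self):
        visits, labels = self.build()
        out = classify_all(visits, labels)
        analysis, flow = build_analysis_set(out)
        assert flow.n_input == len(self.CASES)
        assert flow.n_input == flow.n_oedema_excluded + flow.n_other_excluded + flow.n_analysis
        assert flow.n_analysis == flow.n_recovered + flow.n_non_responder
        assert flow.n_oedema_excluded == 1
        # no child in both the analysis set and the exclusion tally
        excluded_ids = set(out.loc[out["final_label"] == "excluded", "child_id"])
        assert not excluded_ids & set(analysis["child_id"])

    def test_reclassification_only_widens_analysis_set(self):
        visits, labels = self.build()
        out = classify_all(visits, labels)
        analysis, _ = build_analysis_set(out)
        kept_outright = set(
            labels.loc[labels["original_label"].isin(["recovered", "non_responder"]),
                       "child_id"]
        ) - set(out.loc[out["exclusion_reason"] == "oedema_at_admission", "child_id"])
        assert kept_outright <= set(analysis["child_id"])

    def test_flowcounts_invariant_guard(self):
        with pytest.raises(ValueError):
            FlowCounts(10, 1, 1, 9, 5, 4)


def test_determinism_on_cohort(small_cohort, reference):
    from cmamgrowth.cleaning import clean_visits

    cleaned, _ = clean_visits(small_cohort.visits, reference)
    a = classify_all(cleaned, small_cohort.labels)
    b = classify_all(cleaned, small_cohort.labels)
    pd.testing.assert_frame_equal(a, b)
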