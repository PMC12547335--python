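"""Equalized-odds discrepancy and outcome-disparity arithmetic."""

import numpy as np
import pandas as pd
import pytest

from carepath.exceptions import ArgumentError, UndefinedRateError
from carepath.fairness import (
    disparity_reduction,
    equalized_odds_discrepancy,
    equalized_odds_from_outcomes,
    fairness_report,
    group_event_rates,
    outcome_disparity,
)


def counts_from_rates(tpr, fpr, n_pos=100, n_neg=100):
    tp = round(tpr * n_pos)
    fp = round(fpr * n_neg)
    return (tp, n_pos - tp, fp, n_neg - fp)


def outcomes_frame(ev_sq, ev_rl):
    n = len(ev_sq)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "event_statusquo": np.asarray(ev_sq, int),
        "event_sarsa": np.asarray(ev_rl, int),
        "risk_tertile": ["medium"] * n,
    })


class TestEqualizedOdds:
    def test_two_group_formula(self):
        counts = {"A": counts_from_rates(0.8, 0.2), "B": counts_from_rates(0.7, 0.35)}
        assert equalized_odds_discrepancy(counts) == pytest.approx(15.0)

    def test_identical_groups_zero(self):
        counts = {"A": (8, 2, 3, 7), "B": (8, 2, 3, 7)}
        assert equalized_odds_discrepancy(counts) == pytest.approx(0.0)

    def test_hand_computed_confusion_counts(self):
        # A: TPR 8/10=0.8, FPR 1/10=0.1; B: TPR 6/10=0.6, FPR 3/10=0.3
        counts = {"A": (8, 2, 1, 9), "B": (6, 4, 3, 7)}
        assert equalized_odds_discrepancy(counts) == pytest.approx(20.0)

    def test_multi_group_is_max_over_pairs(self):
        counts = {
            "A": counts_from_rates(0.8, 0.2),
            "B": counts_from_rates(0.7, 0.2),
            "C": counts_from_rates(0.5, 0.2),
        }
        assert equalized_odds_discrepancy(counts) == pytest.approx(30.0)

    def test_two_group_consistency_with_multigroup_restriction(self):
        counts = {
            "A": counts_from_rates(0.9, 0.1),
            "B": counts_from_rates(0.6, 0.25),
            "C": counts_from_rates(0.7, 0.4),
        }
        full = equalized_odds_discrepancy(counts)
        pair_max = max(
            equalized_odds_discrepancy({g: counts[g], h: counts[h]})
            for g, h in (("A", "B"), ("A", "C"), ("B", "C"))
        )
        assert full == pytest.approx(pair_max)

    def test_duplicate_group_does_not_change_maximum(self):
        counts = {"A": counts_from_rates(0.8, 0.2), "B": counts_from_rates(0.6, 0.3)}
        dup = dict(counts, C=counts["B"])
        assert equalized_odds_discrepancy(dup) == equalized_odds_discrepancy(counts)

    def test_scale_free_in_group_sizes(self):
        small = {"A": counts_from_rates(0.8, 0.2, 10, 10),
                 "B": counts_from_rates(0.6, 0.3, 10, 10)}
        large = {"A": counts_from_rates(0.8, 0.2, 1000, 1000),
                 "B": counts_from_rates(0.6, 0.3, 1000, 1000)}
        assert equalized_odds_discrepancy(small) == pytest.approx(
            equalized_odds_discrepancy(large)
        )

    def test_group_without_positives_names_the_group(self):
        counts = {"A": (8, 2, 1, 9), "empty_pos": (0, 0, 3, 7)}
        with pytest.raises(UndefinedRateError, match="empty_pos"):
            equalized_odds_discrepancy(counts)

    def test_single_group_rejected(self):
        with pytest.raises(ArgumentError):
            equalized_odds_discrepancy({"A": (1, 1, 1, 1)})


class TestOutcomeDisparity:
    def test_equal_groups_zero(self):
        out = outcomes_frame([1, 1, 0, 0], [1, 0, 1, 0])
        groups = np.array(["a", "a", "b", "b"])  # 50% in each group, both arms
        assert outcome_disparity(out, groups, "sarsa") == pytest.approx(0.0)

    def test_two_group_difference(self):
        # group a: 40% of 10; group b: 45.3% of 1000 -> disparity 5.3
        ev = np.concatenate([np.repeat([1, 0], [4, 6]), np.repeat([1, 0], [453, 547])])
        groups = np.array(["a"] * 10 + ["b"] * 1000)
        out = outcomes_frame(ev, ev)
        assert outcome_disparity(out, groups, "statusquo") == pytest.approx(5.3)

    def test_three_groups_max_pairwise(self):
        ev = np.concatenate([
            np.repeat([1, 0], [40, 60]),
            np.repeat([1, 0], [44, 56]),
            np.repeat([1, 0], [49, 51]),
        ])
        groups = np.repeat(["a", "b", "c"], 100)
        out = outcomes_frame(ev, ev)
        assert outcome_disparity(out, groups, "sarsa") == pytest.approx(9.0)

    def test_permutation_invariant_to_labels(self):
        rng = np.random.default_rng(3)
        ev = rng.integers(0, 2, 90)
        groups = np.repeat(["x", "y", "z"], 30)
        out = outcomes_frame(ev, ev)
        renamed = np.array([{"x": "z", "y": "x", "z": "y"}[g] for g in groups])
        assert outcome_disparity(out, groups, "sarsa") == pytest.approx(
            outcome_disparity(out, renamed, "sarsa")
        )

    def test_single_group_rejected(self):
        out = outcomes_frame([1, 0], [0, 1])
        with pytest.raises(ArgumentError):
            outcome_disparity(out, np.array(["a", "a"]), "sarsa")


class TestDisparityReduction:
    @pytest.mark.parametrize(
        "d_sq,d_rl,absolute,relative",
        [(5.3, 3.8, 1.5, 28.3), (8.9, 5.6, 3.3, 37.1), (4.0, 4.0, 0.0, 0.0)],
    )
    def test_published_reduction_arithmetic(self, d_sq, d_rl, absolute, relative):
        a, r = disparity_reduction(d_sq, d_rl)
        assert a == pytest.approx(absolute)
        assert round(r, 1) == relative

    def test_zero_baseline_relative_undefined(self):
        a, r = disparity_reduction(0.0, 2.0)
        assert a == -2.0
        assert r is None

    def test_negative_baseline_rejected(self):
        with pytest.raises(ArgumentError):
            disparity_reduction(-1.0, 0.0)


class TestFairnessReport:
    def test_report_structure_and_small_group_flagging(self):
        rng = np.random.default_rng(8)
        n = 120
        out = outcomes_frame(rng.integers(0, 2, n), rng.integers(0, 2, n))
        groups = np.array(["big"] * 110 + ["tiny"] * 10)
        rep = fairness_report(out, {"gender": groups})
        attr = rep["gender"]
        assert attr.small_groups == ("tiny",)
        assert attr.disparity_statusquo >= 0
        expected_abs = attr.disparity_statusquo - attr.disparity_sarsa
        assert attr.reduction == pytest.approx(expected_abs)
        assert set(attr.rates_sarsa) == {"big", "tiny"}

    def test_benefit_indicator_equalized_odds_runs(self):
        out = outcomes_frame([1, 1, 0, 0, 1, 0], [0, 1, 0, 0, 1, 0])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        val = equalized_odds_from_outcomes(out, groups)
        assert val >= 0
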