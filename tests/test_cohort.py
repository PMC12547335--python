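"""Synthetic cohort generation, summaries, splitting, and environment rollouts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from carepath.cohort import (
    DEFAULT_PREVALENCE,
    CohortConfig,
    EnvironmentParams,
    assign_tertiles,
    cohort_summary,
    generate_cohort,
    simulate_cohort,
    simulate_trajectory,
    split_cohort,
    split_sizes,
    summary_percentage,
)
from carepath.exceptions import ArgumentError, EmptyCohortError, SafetyViolationError
from carepath.features import STATE_FEATURES, WATCHFUL_WAITING
from carepath.policies import BehaviorPolicy, FixedDomainPolicy


class TestGenerateCohort:
    def test_seeded_determinism(self, env):
        cfg = CohortConfig(n_patients=300, seed=42)
        a = generate_cohort(cfg, env)
        b = generate_cohort(cfg, env)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_cohort(self, env):
        out = generate_cohort(CohortConfig(n_patients=0), env)
        assert len(out) == 0
        assert set(STATE_FEATURES) <= set(out.columns)

    def test_negative_n_rejected(self):
        with pytest.raises(ArgumentError):
            CohortConfig(n_patients=-1)

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ArgumentError):
            CohortConfig(n_patients=10, prevalence={"hypertension": 1.4})

    def test_marginals_within_99pct_binomial_interval(self, env):
        """Each attribute proportion falls in the exact 99% binomial interval."""
        cfg = CohortConfig(n_patients=3175, seed=42)
        cohort = generate_cohort(cfg, env)
        for attr, p in DEFAULT_PREVALENCE.items():
            lo, hi = stats.binom.interval(0.99, cfg.n_patients, p)
            count = cohort[attr].sum()
            assert lo <= count <= hi, f"{attr}: {count} outside [{lo}, {hi}]"
        # female marginal from the gender categorical
        lo, hi = stats.binom.interval(0.99, cfg.n_patients, 0.658)
        assert lo <= cohort["female"].sum() <= hi

    def test_ages_truncated_at_zero(self, env):
        cohort = generate_cohort(CohortConfig(n_patients=2000, seed=1), env)
        assert (cohort["age_years"] >= 0).all()

    def test_risk_scores_and_tertiles(self, small_cohort):
        assert small_cohort["risk_score"].between(0, 1).all()
        counts = small_cohort["risk_tertile"].value_counts()
        assert set(counts.index) == {"high", "medium", "low"}
        # tied risk values land in one tertile, so thirds are approximate
        n = len(small_cohort)
        assert counts.between(0.25 * n, 0.45 * n).all()


class TestCohortSummary:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(2089, 3175, 65.8), (1371, 3175, 43.2), (0, 100, 0.0)],
    )
    def test_percentage_rounding(self, count, total, expected):
        assert summary_percentage(count, total) == expected

    def test_summary_counts_match_columns(self, small_cohort):
        table = cohort_summary(small_cohort)
        row = table[table["attribute"] == "hypertension"].iloc[0]
        assert row["n"] == small_cohort["hypertension"].sum()
        assert row["pct"] == round(100 * row["n"] / len(small_cohort), 1)

    def test_empty_cohort_raises(self, env):
        empty = generate_cohort(CohortConfig(n_patients=0), env)
        with pytest.raises(EmptyCohortError):
            cohort_summary(empty)


class TestSplitCohort:
    @pytest.mark.parametrize(
        "n,expected",
        [(3175, (2222, 635, 318)), (100, (70, 20, 10)), (10, (7, 2, 1))],
    )
    def test_split_sizes(self, n, expected):
        assert split_sizes(n) == expected

    def test_bad_proportions_rejected(self):
        with pytest.raises(ArgumentError):
            split_sizes(100, (0.5, 0.2, 0.2))

    def test_partition_disjoint_and_exhaustive(self, env):
        cohort = generate_cohort(CohortConfig(n_patients=1500, seed=5), env)
        train, val, test = split_cohort(cohort, seed=7)
        ids = [set(part["patient_id"]) for part in (train, val, test)]
        assert ids[0] | ids[1] | ids[2] == set(cohort["patient_id"])
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])
        assert (len(train), len(val), len(test)) == split_sizes(1500)

    def test_stratification_balances_event_prevalence(self, env):
        cohort = generate_cohort(CohortConfig(n_patients=2000, seed=9), env)
        parts = split_cohort(cohort, seed=11)
        prevalences = [
            ((p["baseline_ed_flag"] + p["baseline_hosp_flag"]) > 0).mean() for p in parts
        ]
        assert max(prevalences) - min(prevalences) < 0.02

    def test_deterministic_given_seed(self, small_cohort):
        a = split_cohort(small_cohort, seed=3)
        b = split_cohort(small_cohort, seed=3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestTertiles:
    def test_nine_patients_three_per_tertile(self):
        risk = np.arange(1, 10) / 10.0
        labels = assign_tertiles(risk)
        counts = pd.Series(labels).value_counts()
        assert counts["low"] == counts["medium"] == counts["high"] == 3


class TestSimulate:
    def test_zero_horizon_has_only_initial_state(self, small_cohort, behavior, env):
        traj = simulate_trajectory(small_cohort.iloc[0], behavior, env, horizon=0, seed=1)
        assert traj.horizon == 0
        assert traj.states.shape == (1, 47)

    def test_seeded_determinism(self, small_cohort, behavior, env):
        a = simulate_cohort(small_cohort, behavior, env, 4, seed=5)
        b = simulate_cohort(small_cohort, behavior, env, 4, seed=5)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.actions, b.actions)
        assert np.array_equal(a.rewards, b.rewards)

    def test_null_environment_policy_invariance(self, env):
        """With rho=1 and q=0 interventions cannot move the event rate."""
        null_env = EnvironmentParams(rho_matched=1.0, q_resolve=0.0)
        cohort = generate_cohort(CohortConfig(n_patients=10_000, seed=21), null_env)
        r_matched = simulate_cohort(
            cohort, FixedDomainPolicy(True), null_env, 6, seed=31
        ).any_event()
        r_never = simulate_cohort(
            cohort, FixedDomainPolicy(False), null_env, 6, seed=32
        ).any_event()
        count = np.array([r_matched.sum(), r_never.sum()])
        nobs = np.array([r_matched.size, r_never.size])
        from statsmodels.stats.proportion import proportions_ztest

        _, p = proportions_ztest(count, nobs)
        assert p > 0.01

    def test_matched_policy_reduces_events_when_rho_half(self, env):
        """rho=0.5: always-matched beats never-matched over 10,000 rollouts."""
        cohort = generate_cohort(CohortConfig(n_patients=10_000, seed=23), env)
        r_matched = simulate_cohort(
            cohort, FixedDomainPolicy(True), env, 6, seed=41
        ).any_event().mean()
        r_never = simulate_cohort(
            cohort, FixedDomainPolicy(False), env, 6, seed=42
        ).any_event().mean()
        assert r_matched < r_never

    def test_monotone_hazard_in_risk_increments(self, behavior):
        """Raising any log-odds increment never lowers the event rate (CRN)."""
        from carepath.cohort import DEFAULT_LOG_ODDS_INCREMENTS, draw_environment_noise

        cfg = CohortConfig(n_patients=1500, seed=13)
        for feat in ("hypertension", "chf", "baseline_ed_flag"):
            rates = []
            for inc in (0.1, 0.5, 1.0):
                increments = dict(DEFAULT_LOG_ODDS_INCREMENTS)
                increments[feat] = inc
                env_k = EnvironmentParams(log_odds_increments=increments)
                cohort = generate_cohort(cfg, env_k)
                noise = draw_environment_noise(len(cohort), 6, seed=77)
                batch = simulate_cohort(cohort, behavior, env_k, 6, seed=78, noise=noise)
                rates.append(batch.any_event().mean())
            assert rates == sorted(rates), f"{feat}: {rates}"

    def test_masked_policy_action_raises(self, small_cohort, env):
        class BadPolicy:
            def select(self, states, masks, rng, step=0):
                # childcare assistance regardless of household composition
                return np.full(states.shape[0], 7)

        with pytest.raises(SafetyViolationError):
            simulate_cohort(small_cohort, BadPolicy(), env, 2, seed=1)

    def test_trajectory_frame_layout(self, small_trajectories):
        frame = small_trajectories.to_frame()
        assert len(frame) == small_trajectories.n_patients * small_trajectories.horizon
        assert {"patient_id", "step", "action", "reward", "event"} <= set(frame.columns)
        assert set(STATE_FEATURES) <= set(frame.columns)
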