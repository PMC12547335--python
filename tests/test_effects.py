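"""Effect metrics, paired rollouts, bootstrap intervals, doubly robust AIPW."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carepath.cohort import CohortConfig, assign_tertiles, generate_cohort, simulate_cohort
from carepath.effects import (
    bootstrap_ci,
    doubly_robust_ate,
    effect_estimate,
    estimate_effects,
    paired_env_outcomes,
    rollout_paired,
    stratified_effects,
)
from carepath.exceptions import ArgumentError, NotFittedError
from carepath.policies import BehaviorPolicy, FixedDomainPolicy
from carepath.transition import TransitionModel, TransitionModelSpec, fit_transition_model


def outcomes_frame(ev_sq, ev_rl, tertiles=None):
    n = len(ev_sq)
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "event_statusquo": np.asarray(ev_sq, dtype=int),
        "event_sarsa": np.asarray(ev_rl, dtype=int),
        "risk_tertile": tertiles if tertiles is not None else ["medium"] * n,
    })


def frame_with_rates(rate_sq, rate_rl, n=100):
    ev_sq = np.zeros(n, int)
    ev_sq[: int(round(rate_sq * n))] = 1
    ev_rl = np.zeros(n, int)
    ev_rl[: int(round(rate_rl * n))] = 1
    return outcomes_frame(ev_sq, ev_rl)


class TestEffectEstimate:
    def test_published_rate_pair_arithmetic(self):
        """Rates 58%/46% give ARR 12.0 pp, RRR 20.7%, NNT 8.3."""
        est = effect_estimate(frame_with_rates(0.58, 0.46))
        assert est.arr == pytest.approx(12.0)
        assert round(est.rrr, 1) == 20.7
        assert round(est.nnt, 1) == 8.3
        assert est.nnh == np.inf
        rounded = est.rounded()
        assert rounded["arr_pp"] == 12.0
        assert rounded["rrr_pct"] == 20.7
        assert rounded["nnt"] == 8.3
        assert rounded["nnh"] == "infinite"

    def test_null_effect_gives_infinite_nnt(self):
        est = effect_estimate(frame_with_rates(0.5, 0.5))
        assert est.arr == 0.0
        assert est.nnt == np.inf

    def test_benefit_only_pattern_gives_infinite_nnh(self):
        est = effect_estimate(outcomes_frame([1, 1, 0, 0], [0, 1, 0, 0]))
        assert est.nnh == np.inf
        assert est.arr > 0

    def test_empty_outcomes_rejected(self):
        with pytest.raises(ArgumentError):
            effect_estimate(outcomes_frame([], []))

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=60))
    def test_identity_chain(self, pairs):
        """RRR·rate_sq = ARR and NNT·ARR = 100 (when finite), to 1e-9."""
        ev_sq, ev_rl = zip(*pairs)
        est = effect_estimate(outcomes_frame(ev_sq, ev_rl))
        assert est.arr == pytest.approx(
            100.0 * (est.rate_statusquo - est.rate_sarsa), abs=1e-9
        )
        if est.rate_statusquo > 0:
            assert est.rrr * est.rate_statusquo == pytest.approx(est.arr, abs=1e-9)
        if np.isfinite(est.nnt):
            assert est.nnt * est.arr == pytest.approx(100.0, abs=1e-9)


class TestBootstrap:
    def test_constant_outcomes_zero_width_interval(self):
        ci = bootstrap_ci(outcomes_frame([1] * 20, [1] * 20), n_boot=200, seed=1)
        assert ci["arr"] == (0.0, 0.0)

    def test_deterministic_given_seed(self):
        frame = frame_with_rates(0.6, 0.4, n=80)
        assert bootstrap_ci(frame, seed=9) == bootstrap_ci(frame, seed=9)

    def test_interval_contains_point_estimate(self):
        frame = frame_with_rates(0.58, 0.46, n=200)
        est = estimate_effects(frame, n_boot=500, seed=3)
        lo, hi = est.ci["arr"]
        assert lo <= est.arr <= hi

    def test_nnt_interval_transforms_arr_interval(self):
        frame = frame_with_rates(0.58, 0.46, n=200)
        ci = bootstrap_ci(frame, n_boot=500, seed=3)
        arr_lo, arr_hi = ci["arr"]
        assert ci["nnt"] == (100.0 / arr_hi, 100.0 / arr_lo)

    def test_arr_interval_crossing_zero_maps_to_infinite_nnt_bound(self):
        rng = np.random.default_rng(5)
        frame = outcomes_frame(rng.integers(0, 2, 40), rng.integers(0, 2, 40))
        ci = bootstrap_ci(frame, n_boot=400, seed=6)
        arr_lo, _ = ci["arr"]
        assert arr_lo < 0
        assert ci["nnt"][1] == np.inf


class TestStratified:
    def test_single_tertile_equals_overall(self):
        frame = frame_with_rates(0.6, 0.4, n=60)
        strat = stratified_effects(frame, n_boot=50, seed=1)
        overall = effect_estimate(frame)
        assert strat["medium"].arr == pytest.approx(overall.arr)
        assert strat["high"].flagged_empty and strat["low"].flagged_empty

    def test_three_patients_per_tertile(self):
        risk = np.arange(1, 10) / 10.0
        tert = assign_tertiles(risk)
        frame = outcomes_frame(np.ones(9, int), np.zeros(9, int), tertiles=tert)
        strat = stratified_effects(frame, n_boot=20, seed=2)
        assert all(strat[t].n == 3 for t in ("high", "medium", "low"))

    def test_stronger_effect_for_high_risk_gives_smaller_nnt(self, env, behavior):
        """Ground-truth gradient: the odds-scale matched effect translates to a
        larger absolute reduction for high-risk patients, so NNT(high) <
        NNT(low).  A 6-month window keeps the composite outcome away from the
        ceiling where every high-risk patient has an event in both arms."""
        cohort = generate_cohort(CohortConfig(n_patients=6000, seed=17), env)
        out = paired_env_outcomes(
            cohort, FixedDomainPolicy(False), FixedDomainPolicy(True), env, 6, seed=19
        )
        strat = {t: effect_estimate(out[out["risk_tertile"] == t]) for t in ("high", "low")}
        assert strat["high"].nnt < strat["low"].nnt


@pytest.fixture(scope="module")
def fitted_model(small_trajectories):
    return fit_transition_model(small_trajectories, TransitionModelSpec(epochs=4), seed=31)


class TestPairedRollouts:
    def test_identical_policies_give_exactly_zero_arr(self, small_cohort, behavior,
                                                      fitted_model):
        out = rollout_paired(small_cohort, behavior, behavior, fitted_model, 6, seed=41)
        assert (out["event_statusquo"] == out["event_sarsa"]).all()
        assert effect_estimate(out).arr == 0.0

    def test_zero_horizon_means_zero_rates(self, small_cohort, behavior, fitted_model):
        out = rollout_paired(small_cohort, behavior, behavior, fitted_model, 0, seed=42)
        est = effect_estimate(out)
        assert est.rate_statusquo == est.rate_sarsa == 0.0

    def test_unfitted_model_rejected(self, small_cohort, behavior):
        with pytest.raises(NotFittedError):
            rollout_paired(small_cohort, behavior, behavior,
                           TransitionModel(TransitionModelSpec(epochs=1)), 6, seed=1)

    def test_env_paired_identical_policies_zero_arr(self, small_cohort, behavior, env):
        out = paired_env_outcomes(small_cohort, behavior, behavior, env, 6, seed=43)
        assert effect_estimate(out).arr == 0.0


class TestDoublyRobust:
    @staticmethod
    def _simulate(n, true_arr_pp, seed, confounded=True):
        """Binary-outcome observational data with a known risk difference."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        logit_e = 0.8 * X[:, 0] - 0.5 * X[:, 1] if confounded else np.zeros(n)
        e = 1.0 / (1.0 + np.exp(-logit_e))
        a = (rng.random(n) < e).astype(int)
        p0 = 1.0 / (1.0 + np.exp(-(-0.2 + 0.9 * X[:, 0] + 0.6 * X[:, 2])))
        p1 = np.clip(p0 - true_arr_pp / 100.0, 0.01, 0.99)
        y = (rng.random(n) < np.where(a == 1, p1, p0)).astype(int)
        return X, a, y

    def test_recovers_known_effect_with_correct_nuisances(self):
        X, a, y = self._simulate(5000, true_arr_pp=10.0, seed=61)
        est, _ = doubly_robust_ate(X, a, y, n_boot=10, seed=1)
        assert est == pytest.approx(10.0, abs=2.0)

    def test_double_robustness_to_misspecified_propensity(self):
        from sklearn.dummy import DummyClassifier

        X, a, y = self._simulate(5000, true_arr_pp=10.0, seed=62)
        est, _ = doubly_robust_ate(
            X, a, y, propensity_model=DummyClassifier(strategy="prior"),
            n_boot=10, seed=2,
        )
        assert est == pytest.approx(10.0, abs=2.0)

    def test_null_effect_covered_by_interval(self):
        X, a, y = self._simulate(3000, true_arr_pp=0.0, seed=63)
        est, (lo, hi) = doubly_robust_ate(X, a, y, n_boot=100, seed=3)
        assert lo <= 0.0 <= hi

    def test_bad_clip_bounds_rejected(self):
        X, a, y = self._simulate(200, 0.0, seed=64)
        with pytest.raises(ArgumentError):
            doubly_robust_ate(X, a, y, clip=(0.0, 0.99), n_boot=2)
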