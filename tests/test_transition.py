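"""Transition-model fitting and calibration diagnostics."""

import itertools

import numpy as np
import pytest

from carepath.cohort import (
    CohortConfig,
    EnvironmentParams,
    generate_cohort,
    monthly_event_prob,
    simulate_cohort,
)
from carepath.exceptions import ArgumentError, FitError, NotFittedError
from carepath.features import feature_index
from carepath.transition import (
    TransitionModel,
    TransitionModelSpec,
    auc_score,
    calibration_report,
    expected_calibration_error,
    fit_transition_model,
)

_FAST_SPEC = TransitionModelSpec(epochs=3)


@pytest.fixture(scope="module")
def fitted_setup(env, behavior):
    """5,000-patient behavior rollout and a fully fitted transition model."""
    cohort = generate_cohort(CohortConfig(n_patients=5000, seed=3), env)
    traj = simulate_cohort(cohort, behavior, env, horizon=6, seed=4)
    model = fit_transition_model(traj, seed=5)
    return cohort, traj, model


def _true_event_probs(traj, env):
    """Oracle per-step event probability for each logged (state, action)."""
    from carepath.cohort import _odds_multiply
    from carepath.mdp import _ACTION_DOMAIN_IDX

    T = traj.horizon
    S = traj.states[:, :T].reshape(-1, 47)
    A = traj.actions.reshape(-1)
    p = monthly_event_prob(S, env)
    need_cols = [feature_index(f"need_{d}") for d in ("medical", "behavioral", "social")]
    need = S[:, need_cols]
    dom = np.where(need.sum(axis=1) > 0, need.argmax(axis=1), -1)
    matched = (dom >= 0) & (_ACTION_DOMAIN_IDX[A] == dom)
    return np.where(matched, _odds_multiply(p, env.rho_matched), p)


class TestFit:
    def test_deterministic_given_seed(self, small_trajectories):
        m1 = fit_transition_model(small_trajectories, _FAST_SPEC, seed=9)
        m2 = fit_transition_model(small_trajectories, _FAST_SPEC, seed=9)
        for w1, w2 in zip(m1.net.get_weights(), m2.net.get_weights()):
            assert np.array_equal(w1, w2)

    def test_single_class_events_rejected(self, small_trajectories):
        import copy

        degenerate = copy.deepcopy(small_trajectories)
        degenerate.events[:] = False
        with pytest.raises(FitError, match="event=0"):
            fit_transition_model(degenerate, _FAST_SPEC)

    def test_unfitted_model_refuses_to_predict(self):
        model = TransitionModel(_FAST_SPEC)
        with pytest.raises(NotFittedError):
            model.predict(np.zeros((1, 47)), np.array([0]))

    def test_event_probabilities_recover_truth(self, fitted_setup, env):
        """Mean absolute error vs the generator's true hazard below 0.05."""
        _, traj, model = fitted_setup
        T = traj.horizon
        S = traj.states[:, :T].reshape(-1, 47)
        A = traj.actions.reshape(-1)
        pred = model.event_probability(S, A)
        mae = np.abs(pred - _true_event_probs(traj, env)).mean()
        assert mae < 0.05

    def test_calibration_slope_near_one_on_simulated_data(self, fitted_setup):
        _, traj, model = fitted_setup
        T = traj.horizon
        S = traj.states[:, :T].reshape(-1, 47)
        pred = model.event_probability(S, traj.actions.reshape(-1))
        report = calibration_report(pred, traj.events.reshape(-1).astype(float))
        assert 0.8 <= report.calibration_slope <= 1.2

    def test_checkpoint_round_trip(self, tmp_path, small_trajectories):
        model = fit_transition_model(small_trajectories, _FAST_SPEC, seed=2)
        model.save(tmp_path / "tm.npz")
        loaded = TransitionModel.load(tmp_path / "tm.npz")
        S = small_trajectories.states[:4, 0]
        A = np.array([0, 1, 2, 8])
        assert np.allclose(
            model.event_probability(S, A), loaded.event_probability(S, A)
        )

    def test_ensemble_averages_members_and_round_trips(self, tmp_path,
                                                       small_trajectories):
        from carepath.transition import TransitionEnsemble, load_transition_checkpoint

        spec = TransitionModelSpec(epochs=2, ensemble_members=2)
        ens = fit_transition_model(small_trajectories, spec, seed=7)
        assert isinstance(ens, TransitionEnsemble) and ens.fitted
        S = small_trajectories.states[:6, 0]
        A = np.arange(6) % 9
        mean_manual = np.mean(
            [m.event_probability(S, A) for m in ens.members], axis=0
        )
        assert np.allclose(ens.event_probability(S, A), mean_manual)
        ens.save(tmp_path / "ens.npz")
        loaded = load_transition_checkpoint(tmp_path / "ens.npz")
        assert np.allclose(loaded.event_probability(S, A), mean_manual)

    def test_immutable_features_not_predicted(self):
        """Demographics and condition flags have no model heads; rollouts pass
        them through by construction."""
        from carepath.transition import BINARY_HEADS, CONTINUOUS_HEADS

        immutable = {"age_std", "female", "race_black", "hypertension", "chf",
                     "housing_instability", "child_in_household"}
        assert immutable.isdisjoint(BINARY_HEADS)
        assert immutable.isdisjoint(CONTINUOUS_HEADS)


class TestCalibrationMetrics:
    def test_two_bin_ece_hand_computed(self):
        pred = np.concatenate([np.full(50, 0.2), np.full(50, 0.8)])
        obs = np.concatenate([
            np.repeat([1.0, 0.0], [10, 40]),   # observed 0.2 in the low bin
            np.repeat([1.0, 0.0], [30, 20]),   # observed 0.6 in the high bin
        ])
        assert expected_calibration_error(pred, obs) == pytest.approx(0.1)

    def test_perfect_predictions(self):
        obs = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        report = calibration_report(obs.copy(), obs)
        assert report.brier == pytest.approx(0.0)
        assert report.auc == pytest.approx(1.0)
        assert report.ece == pytest.approx(0.0)

    def test_auc_matches_brute_force_six_cases(self):
        pred = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        obs = np.array([0, 0, 1, 0, 1, 1])
        pos = pred[obs == 1]
        neg = pred[obs == 0]
        brute = np.mean([
            1.0 if p > n else (0.5 if p == n else 0.0)
            for p, n in itertools.product(pos, neg)
        ])
        assert auc_score(pred, obs) == pytest.approx(brute)

    def test_auc_equals_pairwise_concordance_up_to_n_200(self):
        """Rank-statistic AUC agrees with brute-force pairwise concordance,
        including ties, on random inputs up to n=200."""
        rng = np.random.default_rng(12)
        for n in (10, 57, 200):
            pred = np.round(rng.random(n), 1)  # coarse grid forces ties
            obs = rng.integers(0, 2, size=n)
            if obs.min() == obs.max():
                obs[0] = 1 - obs[0]
            pos, neg = pred[obs == 1], pred[obs == 0]
            brute = np.mean([
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p, q in itertools.product(pos, neg)
            ])
            assert auc_score(pred, obs) == pytest.approx(brute, abs=1e-12)

    def test_ece_zero_for_constant_prediction_at_base_rate(self):
        obs = np.array([1, 0, 0, 1, 0, 0, 0, 1], dtype=float)
        pred = np.full(8, obs.mean())
        assert expected_calibration_error(pred, obs) == pytest.approx(0.0)

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ArgumentError):
            calibration_report(np.array([0.5, 1.2]), np.array([0.0, 1.0]))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ArgumentError):
            calibration_report(np.array([0.5]), np.array([0.0, 1.0]))
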