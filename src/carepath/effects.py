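"""Paired counterfactual evaluation and treatment-effect metrics.

For every test-set patient, two trajectories are rolled out from the same
initial state — one under the status-quo behavior policy and one under the
SARSA-guided policy — using the learned transition model and common random
numbers, so that an identical pair of policies yields an absolute risk
reduction (ARR) of exactly zero.  The per-patient outcome is the composite
acute-care-event indicator: any event within the evaluation horizon.

Effect metrics follow standard epidemiological arithmetic:

* ARR (percentage points) = 100·(rate_statusquo − rate_sarsa)
* RRR (%) = 100·ARR / (100·rate_statusquo)
* NNT = 100 / ARR when ARR > 0, else infinite
* NNH = 100 / (100·(rate_sarsa − rate_statusquo)) when positive, else infinite

Confidence intervals come from patient-level bootstrap resampling (percentile
method); the NNT interval is the transform of the ARR interval, mapping an ARR
interval that crosses zero to an NNT upper bound of infinity.  A doubly robust
(AIPW) estimator combining a propensity model with outcome regressions serves
as the sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import mdp
from .cohort import (
    EnvironmentParams,
    draw_environment_noise,
    simulate_cohort,
)
from .exceptions import ArgumentError, NotFittedError
from .features import STATE_FEATURES, WATCHFUL_WAITING, feature_index
from .transition import TransitionModel

TERTILES = ("high", "medium", "low")

_HX0 = feature_index("hx_substance_use_support")
_STEPS_SINCE_IDX = feature_index("steps_since_last_intervention")
_MONTH_IDX = feature_index("month_index")
_CUM_IDX = feature_index("cum_events")
_MSE_IDX = feature_index("months_since_event")
_RISK_IDX = feature_index("risk_score")
_NEED_COLS = [feature_index(f"need_{d}") for d in ("medical", "behavioral", "social")]
_ED_W = [feature_index(c) for c in ("ed_visits_1m", "ed_visits_3m", "ed_visits_6m")]
_HOSP_W = [feature_index(c) for c in ("hosp_1m", "hosp_3m", "hosp_6m")]


# ---------------------------------------------------------------------------
# Paired rollouts


def _model_rollout(
    states0: np.ndarray,
    policy,
    model: TransitionModel,
    horizon: int,
    noise: np.ndarray,
    policy_seed: int,
    rules=None,
) -> np.ndarray:
    """Any-event indicator per patient from a transition-model rollout."""
    s = states0.copy()
    n = s.shape[0]
    rows = np.arange(n)
    prng = np.random.default_rng(policy_seed)
    any_event = np.zeros(n, dtype=bool)
    for t in range(horizon):
        masks = mdp.compute_masks(s, rules)
        a = np.asarray(policy.select(s, masks, prng, step=t), dtype=int)
        if not masks[rows, a].all():
            raise ArgumentError("policy emitted a masked action during rollout")
        pred = model.predict(s, a)
        ev = noise[:, t, 0] < pred.event_prob
        needs = noise[:, t, 1:4] < pred.need_probs
        is_ed = ev & (noise[:, t, 4] < pred.ed_given_event)
        is_hosp = ev & ~is_ed
        any_event |= ev
        s2 = s.copy()
        s2[rows, _HX0 + a] += 1.0
        active = a != WATCHFUL_WAITING
        s2[:, _STEPS_SINCE_IDX] = np.where(active, 0.0, s2[:, _STEPS_SINCE_IDX] + 1.0)
        s2[:, _MONTH_IDX] += 1.0
        # bookkeeping driven by the sampled event, mirroring the trajectory
        # tables' window accounting; only needs and risk come from the heads
        for w, frac in ((_ED_W, is_ed), (_HOSP_W, is_hosp)):
            s2[:, w[0]] = frac.astype(float)
            s2[:, w[1]] = s2[:, w[1]] * (2.0 / 3.0) + frac
            s2[:, w[2]] = s2[:, w[2]] * (5.0 / 6.0) + frac
        s2[:, _CUM_IDX] += ev
        s2[:, _MSE_IDX] = np.where(ev, 0.0, np.minimum(s2[:, _MSE_IDX] + 1.0, 24.0))
        s2[:, _NEED_COLS] = needs.astype(float)
        s2[:, _RISK_IDX] = np.clip(pred.continuous[:, 0], 0.0, 1.0)
        s = s2
    return any_event


def rollout_paired(
    patients: pd.DataFrame,
    statusquo,
    sarsa,
    model: TransitionModel,
    horizon: int,
    seed: int,
    rules=None,
) -> pd.DataFrame:
    """Paired counterfactual outcomes under the two policies.

    Both arms start from the same initial states and consume the same
    pre-drawn uniform noise and the same policy random stream (common random
    numbers), so identical policies produce identical outcomes exactly.

    Returns a frame with columns ``patient_id``, ``event_statusquo``,
    ``event_sarsa`` and ``risk_tertile``.
    """
    if not getattr(model, "fitted", False):
        raise NotFittedError("transition model must be fitted before rollouts")
    if horizon < 0:
        raise ArgumentError("horizon must be >= 0")
    states0 = patients[list(STATE_FEATURES)].to_numpy(dtype=float)
    n = len(patients)
    noise = draw_environment_noise(n, horizon, seed)
    ev_sq = _model_rollout(states0, statusquo, model, horizon, noise, seed + 1, rules)
    ev_rl = _model_rollout(states0, sarsa, model, horizon, noise, seed + 1, rules)
    return pd.DataFrame({
        "patient_id": patients["patient_id"].to_numpy(),
        "event_statusquo": ev_sq.astype(int),
        "event_sarsa": ev_rl.astype(int),
        "risk_tertile": (
            patients["risk_tertile"].to_numpy()
            if "risk_tertile" in patients
            else np.full(n, "medium", dtype=object)
        ),
    })


def paired_env_outcomes(
    patients: pd.DataFrame,
    statusquo,
    sarsa,
    env: EnvironmentParams,
    horizon: int,
    seed: int,
    rules=None,
) -> pd.DataFrame:
    """Paired outcomes from the *true* synthetic environment (oracle arm).

    Same contract as :func:`rollout_paired` but rolling out in the generator's
    ground-truth dynamics instead of the learned transition model — used for
    policy-improvement checks and for validating model-based rollouts.
    """
    n = len(patients)
    noise = draw_environment_noise(n, horizon, seed)
    kw = dict(env=env, horizon=horizon, seed=seed, rules=rules,
              noise=noise, policy_seed=seed + 1)
    b_sq = simulate_cohort(patients, statusquo, **kw)
    b_rl = simulate_cohort(patients, sarsa, **kw)
    return pd.DataFrame({
        "patient_id": patients["patient_id"].to_numpy(),
        "event_statusquo": b_sq.any_event().astype(int),
        "event_sarsa": b_rl.any_event().astype(int),
        "risk_tertile": (
            patients["risk_tertile"].to_numpy()
            if "risk_tertile" in patients
            else np.full(n, "medium", dtype=object)
        ),
    })


# ---------------------------------------------------------------------------
# Effect metrics


@dataclass(frozen=True)
class EffectEstimate:
    """Point estimates of the paired-policy contrast (CI fields optional)."""

    rate_statusquo: float
    rate_sarsa: float
    arr: float          #: absolute risk reduction, percentage points
    rrr: float          #: relative risk reduction, %
    nnt: float          #: number needed to treat (inf when ARR <= 0)
    nnh: float          #: number needed to harm (inf when no harm)
    n: int
    ci: dict = field(default_factory=dict)
    flagged_empty: bool = False

    def rounded(self) -> dict:
        """Presentation-scale numbers: rates in whole %, ARR/RRR/NNT to 1 dp."""
        return {
            "rate_sarsa_pct": round(100.0 * self.rate_sarsa),
            "rate_statusquo_pct": round(100.0 * self.rate_statusquo),
            "arr_pp": round(self.arr, 1),
            "rrr_pct": round(self.rrr, 1) if np.isfinite(self.rrr) else None,
            "nnt": round(self.nnt, 1) if np.isfinite(self.nnt) else "infinite",
            "nnh": round(self.nnh, 1) if np.isfinite(self.nnh) else "infinite",
        }


def _effect_numbers(rate_sq: float, rate_rl: float) -> tuple[float, float, float, float]:
    arr = 100.0 * (rate_sq - rate_rl)
    rrr = 100.0 * arr / (100.0 * rate_sq) if rate_sq > 0 else np.nan
    nnt = 100.0 / arr if arr > 0 else np.inf
    harm = 100.0 * (rate_rl - rate_sq)
    nnh = 100.0 / harm if harm > 0 else np.inf
    return arr, rrr, nnt, nnh


def effect_estimate(outcomes: pd.DataFrame) -> EffectEstimate:
    """Point estimates of event rates, ARR, RRR, NNT and NNH."""
    if len(outcomes) == 0:
        raise ArgumentError("cannot estimate effects from empty outcomes")
    rate_sq = float(outcomes["event_statusquo"].mean())
    rate_rl = float(outcomes["event_sarsa"].mean())
    arr, rrr, nnt, nnh = _effect_numbers(rate_sq, rate_rl)
    return EffectEstimate(rate_sq, rate_rl, arr, rrr, nnt, nnh, n=len(outcomes))


def bootstrap_ci(
    outcomes: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Percentile bootstrap CIs by patient-level resampling.

    Returns intervals for the arm rates, ARR and RRR; the NNT interval is
    derived by transforming the ARR interval endpoints (an ARR interval
    crossing zero maps to an infinite NNT upper bound).  Deterministic given
    ``seed``.
    """
    if n_boot < 1:
        raise ArgumentError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ArgumentError("level must be in (0, 1)")
    n = len(outcomes)
    if n == 0:
        raise ArgumentError("cannot bootstrap empty outcomes")
    ev_sq = outcomes["event_statusquo"].to_numpy(dtype=float)
    ev_rl = outcomes["event_sarsa"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    rate_sq = ev_sq[idx].mean(axis=1)
    rate_rl = ev_rl[idx].mean(axis=1)
    arr = 100.0 * (rate_sq - rate_rl)
    with np.errstate(divide="ignore", invalid="ignore"):
        rrr = np.where(rate_sq > 0, arr / rate_sq, np.nan)
    alpha = (1.0 - level) / 2.0

    def pct(x: np.ndarray) -> tuple[float, float]:
        x = x[~np.isnan(x)]
        lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    arr_lo, arr_hi = pct(arr)
    nnt_lo = 100.0 / arr_hi if arr_hi > 0 else np.inf
    nnt_hi = 100.0 / arr_lo if arr_lo > 0 else np.inf
    return {
        "rate_statusquo": pct(rate_sq),
        "rate_sarsa": pct(rate_rl),
        "arr": (arr_lo, arr_hi),
        "rrr": pct(rrr) if np.isfinite(rrr).any() else (np.nan, np.nan),
        "nnt": (nnt_lo, nnt_hi),
        "level": level,
        "n_boot": n_boot,
    }


def estimate_effects(
    outcomes: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EffectEstimate:
    """Point estimates plus bootstrap CIs in one object."""
    est = effect_estimate(outcomes)
    ci = bootstrap_ci(outcomes, n_boot=n_boot, level=level, seed=seed)
    return EffectEstimate(
        est.rate_statusquo, est.rate_sarsa, est.arr, est.rrr, est.nnt, est.nnh,
        n=est.n, ci=ci,
    )


def stratified_effects(
    outcomes: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, EffectEstimate]:
    """Per-risk-tertile effect estimates (high / medium / low).

    An empty stratum is returned flagged (NaN rates, ``flagged_empty=True``)
    rather than silently dropped.
    """
    out: dict[str, EffectEstimate] = {}
    for i, tert in enumerate(TERTILES):
        sub = outcomes[outcomes["risk_tertile"] == tert]
        if len(sub) == 0:
            out[tert] = EffectEstimate(
                np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, n=0,
                flagged_empty=True,
            )
        else:
            out[tert] = estimate_effects(sub, n_boot=n_boot, level=level,
                                         seed=seed + i)
    return out


# ---------------------------------------------------------------------------
# Doubly robust (AIPW) sensitivity analysis


def doubly_robust_ate(
    X: np.ndarray,
    arm: np.ndarray,
    event: np.ndarray,
    propensity_model=None,
    outcome_model=None,
    clip: tuple[float, float] = (0.01, 0.99),
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Augmented-IPW average treatment effect, in ARR percentage points.

    ``arm`` is 1 for SARSA-guided, 0 for status quo; ``event`` the binary
    outcome.  The estimator averages
    ``m1(x) − m0(x) + a·(y − m1(x))/e(x) − (1−a)·(y − m0(x))/(1−e(x))`` over
    patients, with propensities clipped to ``clip``; the result is reported as
    an ARR (status quo minus SARSA) in percentage points, with a patient-level
    bootstrap CI in which nuisance models are refitted per resample.

    Nuisance models default to logistic regressions; anything following the
    sklearn fit/predict_proba protocol may be substituted, and the estimator is
    consistent when either nuisance model is correctly specified.
    """
    X = np.asarray(X, dtype=float)
    arm = np.asarray(arm, dtype=int)
    event = np.asarray(event, dtype=float)
    if not 0.0 < clip[0] < clip[1] < 1.0:
        raise ArgumentError("clip bounds must satisfy 0 < lo < hi < 1")

    def estimate(Xs, As, Ys) -> float:
        prop = propensity_model if propensity_model is not None else LogisticRegression(
            max_iter=1000
        )
        prop.fit(Xs, As)
        e = np.clip(prop.predict_proba(Xs)[:, 1], clip[0], clip[1])
        if e.min() <= 0.0 or e.max() >= 1.0:
            raise ArgumentError("propensity estimates must be clipped inside (0, 1)")
        m = np.empty((len(Ys), 2))
        for a in (0, 1):
            om = outcome_model if outcome_model is not None else LogisticRegression(
                max_iter=1000
            )
            sel = As == a
            if Ys[sel].min() == Ys[sel].max():
                m[:, a] = Ys[sel].mean()
            else:
                om.fit(Xs[sel], Ys[sel])
                m[:, a] = om.predict_proba(Xs)[:, 1]
        psi = (
            m[:, 1] - m[:, 0]
            + As * (Ys - m[:, 1]) / e
            - (1 - As) * (Ys - m[:, 0]) / (1 - e)
        )
        # ATE of arm=1 on events; ARR is its negation in percentage points
        return -100.0 * float(psi.mean())

    point = estimate(X, arm, event)
    rng = np.random.default_rng(seed)
    n = len(event)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        # degenerate resamples (single arm) are redrawn
        while len(np.unique(arm[idx])) < 2:
            idx = rng.integers(0, n, size=n)
        boots[b] = estimate(X[idx], arm[idx], event[idx])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return point, (float(lo), float(hi))
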