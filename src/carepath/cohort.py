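"""Synthetic Medicaid-like cohort generator and ground-truth environment.

The study population this package targets — Medicaid beneficiaries in
multi-state care-management programs — is private, so every downstream stage
runs against seeded synthetic cohorts whose marginals match the published
population characteristics: 65.8% female, mean age 34.5 (SD 18.5), chronic
conditions led by hypertension (43.2%), depression (37.9%) and diabetes
(29.6%), four social-determinant domains, and baseline 6-month utilization of
51.7% (any ED visit) and 23.2% (any hospitalization).

The ground-truth dynamic is a monthly logistic hazard for a composite acute
care event (ED visit or hospitalization).  Each patient may carry one latent
*active need domain* (medical / behavioral / social); an intervention matched
to that domain multiplies the event odds by ``rho_matched`` (≤ 1) for the
current month and resolves the need with probability ``q_resolve``, removing
its hazard contribution permanently.  These dynamics are invented plumbing —
the real-world generative process is unobservable — but they provide the known
truth that parameter-recovery and policy-improvement tests require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import mdp
from .exceptions import ArgumentError, EmptyCohortError, SafetyViolationError
from .features import (
    ACTIONS,
    DOMAINS,
    N_ACTIONS,
    N_STATE_FEATURES,
    STATE_FEATURES,
    WATCHFUL_WAITING,
    feature_index,
)

# ---------------------------------------------------------------------------
# Configuration

#: Published cohort marginals (proportions) used as generator defaults.
DEFAULT_PREVALENCE: dict[str, float] = {
    "hypertension": 0.432,
    "depression": 0.379,
    "diabetes": 0.296,
    "substance_use_disorder": 0.200,
    "copd": 0.150,
    "chf": 0.110,
    "housing_instability": 0.274,
    "food_insecurity": 0.230,
    "transportation_barriers": 0.180,
    "utility_needs": 0.135,
    "baseline_ed_flag": 0.517,
    "baseline_hosp_flag": 0.232,
    # auxiliary attributes not tabulated in the source population; realistic
    # stand-ins for a young Medicaid cohort
    "child_in_household": 0.350,
    "dme_flag": 0.080,
}

DEFAULT_RACE_PROBS: dict[str, float] = {
    "race_asian": 0.010,
    "race_black": 0.118,
    "race_hispanic": 0.051,
    "race_white": 0.133,
    "race_other_multiple": 0.688,
}

DEFAULT_GENDER_PROBS: dict[str, float] = {
    "female": 0.658,
    "male": 0.330,
    "gender_other": 0.012,
}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-generation settings (defaults reproduce the study marginals)."""

    n_patients: int
    horizon: int = 12
    seed: int = 42
    age_mean: float = 34.5
    age_sd: float = 18.5
    prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    race_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE_PROBS))
    gender_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENDER_PROBS))
    #: probability of a positive substance-use screen among patients without a
    #: recorded substance use disorder (screens are always positive with one)
    sud_screen_background: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ArgumentError("n_patients must be >= 0")
        if self.horizon < 0:
            raise ArgumentError("horizon must be >= 0")
        for name, p in {**self.prevalence, **self.race_probs, **self.gender_probs,
                        "sud_screen_background": self.sud_screen_background}.items():
            if not 0.0 <= p <= 1.0:
                raise ArgumentError(f"proportion {name}={p} outside [0, 1]")
        for probs, label in ((self.race_probs, "race"), (self.gender_probs, "gender")):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ArgumentError(f"{label} probabilities must sum to 1")
        if self.age_sd <= 0:
            raise ArgumentError("age_sd must be positive")


#: Baseline monthly event log-odds, set so that the status-quo behavior policy
#: produces a 12-month composite event rate near the published 58%.
DEFAULT_BASELINE_LOG_ODDS = -3.75

#: Per-risk-factor log-odds increments of the monthly hazard.
DEFAULT_LOG_ODDS_INCREMENTS: dict[str, float] = {
    "hypertension": 0.25,
    "depression": 0.30,
    "diabetes": 0.30,
    "substance_use_disorder": 0.40,
    "copd": 0.35,
    "chf": 0.45,
    "housing_instability": 0.30,
    "food_insecurity": 0.25,
    "transportation_barriers": 0.20,
    "utility_needs": 0.15,
    "baseline_ed_flag": 0.50,
    "baseline_hosp_flag": 0.40,
}

#: Default status-quo action propensities when not matching an observed need,
#: qualitatively emulating observed practice patterns (mental-health support
#: and watchful waiting dominate; substance-use support is almost never used).
DEFAULT_BEHAVIOR_BIAS: tuple[float, ...] = (
    0.001,  # substance_use_support
    0.340,  # mental_health_support
    0.200,  # chronic_condition_support
    0.090,  # food_assistance
    0.100,  # housing_assistance
    0.050,  # transportation_assistance
    0.040,  # utility_assistance
    0.020,  # childcare_assistance
    0.159,  # watchful_waiting
)


@dataclass(frozen=True)
class EnvironmentParams:
    """Ground-truth dynamics of the care-management environment."""

    baseline_log_odds: float = DEFAULT_BASELINE_LOG_ODDS
    log_odds_increments: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_ODDS_INCREMENTS)
    )
    #: extra log-odds while any need domain is active
    need_log_odds: float = 0.70
    #: odds multiplier applied the month a matched intervention is delivered
    rho_matched: float = 0.5
    #: probability a matched intervention resolves the active need
    q_resolve: float = 0.3
    #: odds multiplier for unmatched active interventions (1 = no effect)
    unmatched_multiplier: float = 1.0
    #: probability the behavior policy matches the most salient observed need
    behavior_match_prob: float = 0.45
    #: behavior-policy action propensities when not matching
    behavior_action_bias: tuple[float, ...] = DEFAULT_BEHAVIOR_BIAS
    #: share of composite events that are ED visits (vs hospitalizations)
    ed_event_share: float = 0.7
    #: months of static exposure the calculated risk score integrates over
    risk_horizon: int = 12

    def __post_init__(self) -> None:
        if not 0.0 < self.rho_matched <= 1.0:
            raise ArgumentError("rho_matched must be in (0, 1]")
        if not 0.0 <= self.q_resolve <= 1.0:
            raise ArgumentError("q_resolve must be in [0, 1]")
        if self.unmatched_multiplier <= 0:
            raise ArgumentError("unmatched_multiplier must be positive")
        if not 0.0 <= self.behavior_match_prob <= 1.0:
            raise ArgumentError("behavior_match_prob must be in [0, 1]")
        if not 0.0 <= self.ed_event_share <= 1.0:
            raise ArgumentError("ed_event_share must be in [0, 1]")
        bias = np.asarray(self.behavior_action_bias, dtype=float)
        if bias.shape != (N_ACTIONS,) or (bias < 0).any() or bias.sum() <= 0:
            raise ArgumentError("behavior_action_bias must be 9 nonnegative weights")
        for name in self.log_odds_increments:
            feature_index(name)


# ---------------------------------------------------------------------------
# Hazard and risk score

_NEED_COLS = [feature_index(f"need_{d}") for d in DOMAINS]


def _hazard_lp(states: np.ndarray, env: EnvironmentParams) -> np.ndarray:
    """Monthly event linear predictor under watchful waiting (no multiplier)."""
    lp = np.full(states.shape[0], env.baseline_log_odds)
    for name, inc in env.log_odds_increments.items():
        lp += inc * states[:, feature_index(name)]
    any_need = states[:, _NEED_COLS].sum(axis=1) > 0
    lp += env.need_log_odds * any_need
    return lp


def monthly_event_prob(states: np.ndarray, env: EnvironmentParams) -> np.ndarray:
    """Per-month event probability under watchful waiting."""
    return _sigmoid(_hazard_lp(np.atleast_2d(states), env))


def risk_score(states: np.ndarray, env: EnvironmentParams) -> np.ndarray:
    """Calculated risk: probability of ≥1 event over ``env.risk_horizon`` months
    of static exposure under watchful waiting."""
    p = monthly_event_prob(states, env)
    return 1.0 - (1.0 - p) ** env.risk_horizon


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _odds_multiply(p: np.ndarray, m: np.ndarray | float) -> np.ndarray:
    """Multiply probabilities by ``m`` on the odds scale."""
    return m * p / (1.0 - p + m * p)


# ---------------------------------------------------------------------------
# Cohort generation

_HX0 = feature_index("hx_substance_use_support")
_RISK_IDX = feature_index("risk_score")
_DOMAIN_FLAG_IDX = {d: [feature_index(f) for f in mdp.DOMAIN_FLAGS[d]] for d in DOMAINS}


def generate_cohort(config: CohortConfig, env: EnvironmentParams | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort: one row per patient, baseline state features.

    Attributes are independent Bernoulli/categorical/Gaussian draws at the
    configured targets; ages are truncated at 0.  The returned frame carries
    the 47 canonical state features plus ``patient_id``, raw ``age_years``, the
    true (watchful-waiting) risk score and the cohort-relative ``risk_tertile``.
    Deterministic given ``config.seed``.
    """
    env = env or EnvironmentParams()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    X = np.zeros((n, N_STATE_FEATURES))
    df = pd.DataFrame(X, columns=list(STATE_FEATURES))
    df.insert(0, "patient_id", [f"P{i:06d}" for i in range(n)])

    age = np.maximum(rng.normal(config.age_mean, config.age_sd, size=n), 0.0)
    df["age_years"] = age
    df["age_std"] = (age - config.age_mean) / config.age_sd

    gcats = list(config.gender_probs)
    gdraw = rng.choice(len(gcats), size=n, p=[config.gender_probs[g] for g in gcats])
    for j, gname in enumerate(gcats):
        df[gname] = (gdraw == j).astype(float)
    rcats = list(config.race_probs)
    rdraw = rng.choice(len(rcats), size=n, p=[config.race_probs[r] for r in rcats])
    for j, rname in enumerate(rcats):
        df[rname] = (rdraw == j).astype(float)

    for name, p in config.prevalence.items():
        df[name] = (rng.random(n) < p).astype(float)
    df["sud_screen_positive"] = np.maximum(
        df["substance_use_disorder"].to_numpy(),
        (rng.random(n) < config.sud_screen_background).astype(float),
    )

    # trailing utilization windows consistent with the baseline flags
    ed6 = df["baseline_ed_flag"].to_numpy() * (1 + rng.poisson(0.8, size=n))
    ed3 = rng.binomial(ed6.astype(int), 0.5)
    ed1 = rng.binomial(ed3, 1.0 / 3.0)
    hosp6 = df["baseline_hosp_flag"].to_numpy() * (1 + rng.poisson(0.3, size=n))
    hosp3 = rng.binomial(hosp6.astype(int), 0.5)
    hosp1 = rng.binomial(hosp3, 1.0 / 3.0)
    df["ed_visits_6m"], df["ed_visits_3m"], df["ed_visits_1m"] = ed6, ed3, ed1
    df["hosp_6m"], df["hosp_3m"], df["hosp_1m"] = hosp6, hosp3, hosp1
    any_base = (df["baseline_ed_flag"].to_numpy() + df["baseline_hosp_flag"].to_numpy()) > 0
    df["months_since_event"] = np.where(any_base, rng.integers(0, 6, size=n), 12).astype(float)

    # latent active need domain, sampled in proportion to observed flag burden
    states = df[list(STATE_FEATURES)].to_numpy(dtype=float)
    scores = np.stack(
        [states[:, _DOMAIN_FLAG_IDX[d]].sum(axis=1) for d in DOMAINS], axis=1
    )
    total = scores.sum(axis=1)
    if n:
        u = rng.random(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            cum = np.cumsum(scores / total[:, None], axis=1)
        pick = (cum > u[:, None]).argmax(axis=1)
        for j, d in enumerate(DOMAINS):
            df[f"need_{d}"] = ((total > 0) & (pick == j)).astype(float)

    states = df[list(STATE_FEATURES)].to_numpy(dtype=float)
    risk = risk_score(states, env)
    df["risk_score"] = risk
    df["risk_tertile"] = assign_tertiles(risk)
    return df


def assign_tertiles(risk: np.ndarray) -> np.ndarray:
    """Label risk scores high/medium/low by cohort 33.3/66.7 percentile cuts."""
    risk = np.asarray(risk, dtype=float)
    if risk.size == 0:
        return np.array([], dtype=object)
    lo, hi = np.quantile(risk, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(risk <= lo, "low", np.where(risk <= hi, "medium", "high"))
    return labels.astype(object)


# ---------------------------------------------------------------------------
# Summary and splitting

#: Attributes reported in the cohort summary table, in presentation order.
SUMMARY_ATTRIBUTES: tuple[str, ...] = (
    "female",
    "race_asian",
    "race_black",
    "race_hispanic",
    "race_white",
    "race_other_multiple",
    "hypertension",
    "depression",
    "diabetes",
    "substance_use_disorder",
    "copd",
    "chf",
    "housing_instability",
    "food_insecurity",
    "transportation_barriers",
    "utility_needs",
    "baseline_ed_flag",
    "baseline_hosp_flag",
)


def summary_percentage(count: int, total: int) -> float:
    """Percentage of ``count`` in ``total``, rounded to one decimal."""
    if total <= 0:
        raise EmptyCohortError("cannot summarize an empty cohort")
    return round(100.0 * count / total, 1)


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """n (%) per attribute, percentage rounded to one decimal place."""
    if len(cohort) == 0:
        raise EmptyCohortError("cannot summarize an empty cohort")
    n = len(cohort)
    rows = []
    for attr in SUMMARY_ATTRIBUTES:
        count = int(cohort[attr].sum())
        rows.append({"attribute": attr, "n": count, "pct": summary_percentage(count, n)})
    return pd.DataFrame(rows)


def split_sizes(n: int, proportions: Sequence[float] = (0.70, 0.20, 0.10)) -> tuple[int, int, int]:
    """Train/validation/test sizes: floor, round-half-up, remainder."""
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ArgumentError("split proportions must sum to 1")
    if len(proportions) != 3:
        raise ArgumentError("expected exactly three split proportions")
    n_train = int(np.floor(proportions[0] * n))
    n_val = int(np.floor(proportions[1] * n + 0.5))
    n_test = n - n_train - n_val
    if n_test < 0:
        raise ArgumentError("split proportions leave a negative test set")
    return n_train, n_val, n_test


def split_cohort(
    cohort: pd.DataFrame,
    proportions: Sequence[float] = (0.70, 0.20, 0.10),
    stratify_by: str | np.ndarray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified train/validation/test split with exact global sizes.

    Stratification defaults to the baseline acute-care indicator (any prior
    6-month ED visit or hospitalization).  Within each stratum the three
    splits receive a largest-remainder apportionment of the stratum, so event
    prevalence is balanced while the global sizes are exactly
    ``floor(p0·N) / round(p1·N) / remainder``.  Deterministic given ``seed``.
    """
    n = len(cohort)
    targets = split_sizes(n, proportions)
    if stratify_by is None:
        labels = (
            (cohort["baseline_ed_flag"].to_numpy() + cohort["baseline_hosp_flag"].to_numpy()) > 0
        ).astype(int)
    elif isinstance(stratify_by, str):
        labels = cohort[stratify_by].to_numpy()
    else:
        labels = np.asarray(stratify_by)
        if labels.shape[0] != n:
            raise ArgumentError("stratify_by length must match cohort size")

    rng = np.random.default_rng(seed)
    strata: dict = {}
    for lab in pd.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        strata[lab] = idx

    labs = list(strata)
    sizes = np.array([len(strata[lab]) for lab in labs])
    assigned = np.zeros((len(labs), 3), dtype=int)
    remaining = sizes.copy()
    for k in (0, 1):  # train then validation; test takes the remainder
        ideal = sizes * (targets[k] / n) if n else np.zeros(len(labs))
        base = np.minimum(np.floor(ideal).astype(int), remaining)
        short = targets[k] - base.sum()
        frac = ideal - np.floor(ideal)
        order = np.argsort(-frac, kind="stable")
        for i in order:
            if short <= 0:
                break
            if remaining[i] - base[i] > 0:
                base[i] += 1
                short -= 1
        # if still short (capacity limits), top up anywhere possible
        for i in range(len(labs)):
            while short > 0 and remaining[i] - base[i] > 0:
                base[i] += 1
                short -= 1
        assigned[:, k] = base
        remaining -= base
    assigned[:, 2] = remaining

    parts: list[list[np.ndarray]] = [[], [], []]
    for i, lab in enumerate(labs):
        idx = strata[lab]
        a, b = assigned[i, 0], assigned[i, 0] + assigned[i, 1]
        parts[0].append(idx[:a])
        parts[1].append(idx[a:b])
        parts[2].append(idx[b:])
    out = []
    for k in range(3):
        ind = np.sort(np.concatenate(parts[k])) if parts[k] else np.array([], dtype=int)
        out.append(cohort.iloc[ind].reset_index(drop=True))
    return tuple(out)


def group_labels(cohort: pd.DataFrame, attribute: str) -> pd.Series:
    """Categorical group labels for fairness reporting.

    ``attribute`` is ``"gender"`` or ``"race_ethnicity"``; labels are decoded
    from the one-hot state columns.
    """
    if attribute == "gender":
        cols = list(DEFAULT_GENDER_PROBS)
    elif attribute == "race_ethnicity":
        cols = list(DEFAULT_RACE_PROBS)
    else:
        raise ArgumentError(f"unknown group attribute {attribute!r}")
    onehot = cohort[cols].to_numpy()
    return pd.Series(np.array(cols, dtype=object)[onehot.argmax(axis=1)], index=cohort.index)


# ---------------------------------------------------------------------------
# Trajectory simulation

_STEPS_SINCE_IDX = feature_index("steps_since_last_intervention")
_MONTH_IDX = feature_index("month_index")
_CUM_IDX = feature_index("cum_events")
_MSE_IDX = feature_index("months_since_event")
_ED_W = [feature_index(c) for c in ("ed_visits_1m", "ed_visits_3m", "ed_visits_6m")]
_HOSP_W = [feature_index(c) for c in ("hosp_1m", "hosp_3m", "hosp_6m")]

_ACTION_DOMAIN_IDX = mdp._ACTION_DOMAIN_IDX


@dataclass
class TrajectoryBatch:
    """Vectorized rollout for a cohort: arrays aligned on (patient, step).

    ``states`` has shape (n, horizon+1, 47) — the final slice is the terminal
    state.  ``actions``, ``rewards`` and ``events`` have shape (n, horizon).
    """

    patient_ids: np.ndarray
    states: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    events: np.ndarray
    #: per-step indicator that the composite event was an ED visit (vs
    #: hospitalization); None for externally assembled batches
    ed_events: np.ndarray | None = None
    risk_tertile: np.ndarray | None = None

    @property
    def n_patients(self) -> int:
        return self.states.shape[0]

    @property
    def horizon(self) -> int:
        return self.states.shape[1] - 1

    def any_event(self) -> np.ndarray:
        """Composite outcome: any acute event within the horizon, per patient."""
        if self.horizon == 0:
            return np.zeros(self.n_patients, dtype=bool)
        return self.events.any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (patient, step) with state columns."""
        n, T = self.n_patients, self.horizon
        rows = {
            "patient_id": np.repeat(self.patient_ids, T),
            "step": np.tile(np.arange(T), n),
            "action": np.array(ACTIONS, dtype=object)[self.actions.reshape(-1)],
            "reward": self.rewards.reshape(-1),
            "event": self.events.reshape(-1).astype(int),
        }
        frame = pd.DataFrame(rows)
        flat = self.states[:, :T, :].reshape(n * T, N_STATE_FEATURES)
        for j, name in enumerate(STATE_FEATURES):
            frame[name] = flat[:, j]
        return frame


def concat_batches(*batches: TrajectoryBatch) -> TrajectoryBatch:
    """Stack trajectory batches with equal horizons into one batch."""
    if not batches:
        raise ArgumentError("need at least one batch")
    horizons = {b.horizon for b in batches}
    if len(horizons) > 1:
        raise ArgumentError("cannot concatenate batches with different horizons")
    ed = None
    if all(b.ed_events is not None for b in batches):
        ed = np.concatenate([b.ed_events for b in batches])
    tert = None
    if all(b.risk_tertile is not None for b in batches):
        tert = np.concatenate([b.risk_tertile for b in batches])
    return TrajectoryBatch(
        patient_ids=np.concatenate([b.patient_ids for b in batches]),
        states=np.concatenate([b.states for b in batches]),
        actions=np.concatenate([b.actions for b in batches]),
        rewards=np.concatenate([b.rewards for b in batches]),
        events=np.concatenate([b.events for b in batches]),
        ed_events=ed,
        risk_tertile=tert,
    )


@dataclass
class Trajectory:
    """Single-patient rollout: (state, action, reward, next state, event) steps."""

    patient_id: str
    states: np.ndarray  # (horizon+1, 47)
    actions: np.ndarray
    rewards: np.ndarray
    events: np.ndarray

    @property
    def horizon(self) -> int:
        return self.states.shape[0] - 1

    def steps(self) -> list[tuple]:
        return [
            (self.states[t], int(self.actions[t]), float(self.rewards[t]),
             self.states[t + 1], bool(self.events[t]))
            for t in range(self.horizon)
        ]


#: uniform-noise columns drawn per (patient, step).  The true-environment
#: simulator consumes columns 0 (event), 1 (need resolution) and 2 (event
#: type); transition-model rollouts consume 0 (event), 1–3 (need indicators)
#: and 4 (event type).  Sharing column 0 couples event draws across both kinds
#: of rollout from the same seed.
NOISE_COLUMNS = 5


def draw_environment_noise(n: int, horizon: int, seed: int) -> np.ndarray:
    """Uniform draws (n, horizon, NOISE_COLUMNS) for seeded rollouts.

    Pre-drawing and sharing this array across two rollouts implements common
    random numbers for paired counterfactual comparisons.
    """
    return np.random.default_rng(seed).random((n, horizon, NOISE_COLUMNS))


def simulate_cohort(
    cohort: pd.DataFrame,
    policy,
    env: EnvironmentParams,
    horizon: int,
    seed: int,
    rules=None,
    reward_cfg: mdp.RewardConfig | None = None,
    noise: np.ndarray | None = None,
    policy_seed: int | None = None,
) -> TrajectoryBatch:
    """Roll the whole cohort forward under ``policy`` in the true environment.

    Environment stochasticity comes from ``noise`` (or a fresh seeded draw);
    policy stochasticity from a separate stream so that two rollouts sharing
    ``noise`` and ``policy_seed`` are coupled by common random numbers.
    Raises :class:`SafetyViolationError` if the policy emits a masked action.
    """
    if horizon < 0:
        raise ArgumentError("horizon must be >= 0")
    reward_cfg = reward_cfg or mdp.RewardConfig()
    n = len(cohort)
    s = cohort[list(STATE_FEATURES)].to_numpy(dtype=float).copy()
    if noise is None:
        noise = draw_environment_noise(n, horizon, seed)
    if noise.shape[:2] != (n, horizon) or noise.shape[2] < 3:
        raise ArgumentError("noise must have shape (n, horizon, >=3)")
    prng = np.random.default_rng(seed + 1 if policy_seed is None else policy_seed)

    states = np.empty((n, horizon + 1, N_STATE_FEATURES))
    actions = np.empty((n, horizon), dtype=int)
    rewards = np.empty((n, horizon))
    events = np.empty((n, horizon), dtype=bool)
    ed_events = np.empty((n, horizon), dtype=bool)
    states[:, 0] = s
    rows = np.arange(n)

    for t in range(horizon):
        masks = mdp.compute_masks(s, rules)
        a = np.asarray(policy.select(s, masks, prng, step=t), dtype=int)
        if not masks[rows, a].all():
            bad = ACTIONS[int(a[~masks[rows, a]][0])]
            raise SafetyViolationError(f"policy emitted masked action {bad!r}")

        p = monthly_event_prob(s, env)
        need = s[:, _NEED_COLS]
        need_dom = np.where(need.sum(axis=1) > 0, need.argmax(axis=1), -1)
        matched = (need_dom >= 0) & (_ACTION_DOMAIN_IDX[a] == need_dom)
        active = a != WATCHFUL_WAITING
        mult = np.where(matched, env.rho_matched,
                        np.where(active, env.unmatched_multiplier, 1.0))
        p_eff = _odds_multiply(p, mult)
        ev = noise[:, t, 0] < p_eff
        resolved = matched & (noise[:, t, 1] < env.q_resolve)
        is_ed = ev & (noise[:, t, 2] < env.ed_event_share)
        is_hosp = ev & ~is_ed

        s2 = s.copy()
        s2[rows, _HX0 + a] += 1.0
        s2[:, _STEPS_SINCE_IDX] = np.where(active, 0.0, s2[:, _STEPS_SINCE_IDX] + 1.0)
        s2[:, _MONTH_IDX] += 1.0
        # trailing windows decay geometrically toward the window length
        for w, frac, flag in ((_ED_W, is_ed, None), (_HOSP_W, is_hosp, None)):
            s2[:, w[0]] = frac.astype(float)
            s2[:, w[1]] = s2[:, w[1]] * (2.0 / 3.0) + frac
            s2[:, w[2]] = s2[:, w[2]] * (5.0 / 6.0) + frac
        s2[:, _CUM_IDX] += ev
        s2[:, _MSE_IDX] = np.where(ev, 0.0, np.minimum(s2[:, _MSE_IDX] + 1.0, 24.0))
        if resolved.any():
            s2[np.ix_(resolved, _NEED_COLS)] = 0.0
        s2[:, _RISK_IDX] = risk_score(s2, env)

        rewards[:, t] = mdp.compute_rewards(s, a, s2, ev, None, reward_cfg)
        actions[:, t] = a
        events[:, t] = ev
        ed_events[:, t] = is_ed
        s = s2
        states[:, t + 1] = s

    return TrajectoryBatch(
        patient_ids=cohort["patient_id"].to_numpy(),
        states=states,
        actions=actions,
        rewards=rewards,
        events=events,
        ed_events=ed_events,
        risk_tertile=(
            cohort["risk_tertile"].to_numpy() if "risk_tertile" in cohort else None
        ),
    )


def simulate_trajectory(
    patient: pd.Series | pd.DataFrame,
    policy,
    env: EnvironmentParams,
    horizon: int,
    seed: int,
    rules=None,
    reward_cfg: mdp.RewardConfig | None = None,
) -> Trajectory:
    """Single-patient rollout (see :func:`simulate_cohort` for dynamics)."""
    row = patient.to_frame().T if isinstance(patient, pd.Series) else patient
    batch = simulate_cohort(row, policy, env, horizon, seed, rules, reward_cfg)
    return Trajectory(
        patient_id=str(row["patient_id"].iloc[0]),
        states=batch.states[0],
        actions=batch.actions[0],
        rewards=batch.rewards[0],
        events=batch.events[0],
    )
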