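"""Learned one-step patient dynamics for counterfactual rollouts.

The transition model is a feed-forward network taking the 47 state features
plus a 9-way one-hot action encoding and predicting, through three ReLU hidden
layers of 128, 64 and 32 nodes:

* a sigmoid head for the probability of an acute care event this month,
* a sigmoid head for the event type (ED visit vs hospitalization, given an
  event — fitted on event steps only),
* sigmoid heads for the three active-need-domain indicators of the next state,
* linear heads for the continuous mutable features (next risk score, trailing
  utilization windows, months since last event).

Bookkeeping features that are mechanical functions of the sampled event
history (intervention-history counts, steps since last intervention, month
index, cumulative events, trailing utilization windows, months since last
event) are updated by rule during rollouts — only the event, its type, the
need indicators and the risk score are read from the learned heads, which
keeps multi-step rollouts on the data manifold.  Immutable features
(demographics, condition and social flags) pass through unchanged by
construction.

Calibration/discrimination diagnostics follow standard practice: expected
calibration error over equal-width probability bins, AUC as the pairwise rank
statistic, Brier score, a logistic calibration slope, and the Hosmer–Lemeshow
goodness-of-fit test over equal-frequency groups.
"""

from __future__ import annotations

import json
from dataclasses import asdict as asdict_spec_impl, dataclass


def asdict_spec(spec) -> dict:
    return asdict_spec_impl(spec)

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .cohort import TrajectoryBatch
from .exceptions import ArgumentError, ChecksumMismatchError, FitError, NotFittedError
from .features import N_ACTIONS, N_STATE_FEATURES, feature_index, state_dictionary_hash
from .nn import MLP, sigmoid

#: continuous mutable features predicted by linear heads, in head order
CONTINUOUS_HEADS: tuple[str, ...] = (
    "risk_score",
    "ed_visits_1m",
    "ed_visits_3m",
    "ed_visits_6m",
    "hosp_1m",
    "hosp_3m",
    "hosp_6m",
    "months_since_event",
)
#: binary mutable features predicted by sigmoid heads
BINARY_HEADS: tuple[str, ...] = ("need_medical", "need_behavioral", "need_social")

#: fixed scale applied to each continuous target so the squared-error heads
#: contribute comparably to the loss (risk is already in [0,1])
_CONT_SCALES = np.array([1.0, 1.0, 3.0, 6.0, 1.0, 3.0, 6.0, 12.0])

_CONT_IDX = np.array([feature_index(f) for f in CONTINUOUS_HEADS])
_BIN_IDX = np.array([feature_index(f) for f in BINARY_HEADS])


@dataclass(frozen=True)
class TransitionModelSpec:
    """Architecture: 47 + 9 inputs, hidden (128, 64, 32), multi-head output."""

    hidden: tuple[int, int, int] = (128, 64, 32)
    dropout: float = 0.0
    epochs: int = 40
    batch_size: int = 256
    learning_rate: float = 1e-3
    #: per-epoch multiplicative learning-rate decay; the default anneals the
    #: step size so successive fits settle instead of oscillating
    lr_decay: float = 0.93
    event_loss_weight: float = 1.0
    #: loss weight on the need-indicator heads, whose accuracy dominates
    #: multi-step rollout fidelity
    binary_loss_weight: float = 1.0
    #: number of independently seeded members whose predicted probabilities
    #: are averaged; ensembling cancels most fit-seed variance in multi-step
    #: rollout event rates
    ensemble_members: int = 1

    def __post_init__(self) -> None:
        if len(self.hidden) != 3:
            raise ArgumentError("transition model uses exactly three hidden layers")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        # heads: event, event type (ED|event), need indicators, continuous
        n_out = 2 + len(BINARY_HEADS) + len(CONTINUOUS_HEADS)
        return (N_STATE_FEATURES + N_ACTIONS, *self.hidden, n_out)


@dataclass
class TransitionPrediction:
    """One-step predictions for a batch of (state, action) pairs."""

    event_prob: np.ndarray          # (n,)
    ed_given_event: np.ndarray      # (n,) P(event is an ED visit | event)
    need_probs: np.ndarray          # (n, 3) in BINARY_HEADS order
    continuous: np.ndarray          # (n, len(CONTINUOUS_HEADS)), feature scale


class TransitionModel:
    """Fitted one-step dynamics model (see module docstring)."""

    def __init__(self, spec: TransitionModelSpec = TransitionModelSpec(), seed: int = 42):
        self.spec = spec
        self.seed = seed
        self.net = MLP(spec.layer_sizes, dropout=spec.dropout, seed=seed)
        self.feature_hash = state_dictionary_hash()
        self.fitted = False

    # -- fitting -----------------------------------------------------------
    def fit(self, trajectories: TrajectoryBatch) -> "TransitionModel":
        n, T = trajectories.n_patients, trajectories.horizon
        if n == 0 or T == 0:
            raise ArgumentError("trajectories contain no transitions")
        events = trajectories.events.reshape(-1).astype(float)
        uniq = np.unique(events)
        if uniq.size < 2:
            label = int(uniq[0]) if uniq.size else "none"
            raise FitError(
                f"cannot fit event head: all transitions have event={label}"
            )
        S = trajectories.states[:, :T].reshape(n * T, -1)
        S2 = trajectories.states[:, 1:].reshape(n * T, -1)
        A = trajectories.actions.reshape(-1)
        X = np.concatenate([S, np.eye(N_ACTIONS)[A]], axis=1)
        y_bin = S2[:, _BIN_IDX]
        y_cont = S2[:, _CONT_IDX] / _CONT_SCALES
        if trajectories.ed_events is not None:
            ed = trajectories.ed_events.reshape(-1).astype(float)
        else:
            ed = events.copy()  # no type labels: treat every event as an ED visit

        rng = np.random.default_rng(self.seed)
        net = self.net
        w_ev = self.spec.event_loss_weight
        w_bin = self.spec.binary_loss_weight
        nb = len(BINARY_HEADS)
        lr = self.spec.learning_rate
        for _ in range(self.spec.epochs):
            perm = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0], self.spec.batch_size):
                idx = perm[start:start + self.spec.batch_size]
                out, cache = net.forward(X[idx], train=True)
                B = len(idx)
                dout = np.empty_like(out)
                # BCE gradients for sigmoid heads; MSE for linear heads
                dout[:, 0] = w_ev * (sigmoid(out[:, 0]) - events[idx]) / B
                # the type head learns P(ED | event): gradient on event steps only
                dout[:, 1] = events[idx] * (sigmoid(out[:, 1]) - ed[idx]) / B
                dout[:, 2:2 + nb] = w_bin * (sigmoid(out[:, 2:2 + nb]) - y_bin[idx]) / B
                dout[:, 2 + nb:] = (out[:, 2 + nb:] - y_cont[idx]) / B
                net.adam_step(net.backward(cache, dout), lr)
            lr *= self.spec.lr_decay
        self.fitted = True
        return self

    # -- prediction --------------------------------------------------------
    def predict(self, states: np.ndarray, actions: np.ndarray) -> TransitionPrediction:
        if not self.fitted:
            raise NotFittedError("transition model has not been fitted")
        states = np.atleast_2d(np.asarray(states, dtype=float))
        a = np.asarray(actions, dtype=int)
        X = np.concatenate([states, np.eye(N_ACTIONS)[a]], axis=1)
        out = self.net.predict(X)
        out = np.atleast_2d(out)
        nb = len(BINARY_HEADS)
        return TransitionPrediction(
            event_prob=sigmoid(out[:, 0]),
            ed_given_event=sigmoid(out[:, 1]),
            need_probs=sigmoid(out[:, 2:2 + nb]),
            continuous=out[:, 2 + nb:] * _CONT_SCALES,
        )

    def event_probability(self, states: np.ndarray, actions: np.ndarray) -> np.ndarray:
        return self.predict(states, actions).event_prob

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "kind": "transition_model",
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict_spec(self.spec).items()},
            "feature_hash": self.feature_hash,
            "fitted": self.fitted,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TransitionModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["feature_hash"] != state_dictionary_hash():
                raise ChecksumMismatchError(
                    "checkpoint was trained under a different state-feature dictionary"
                )
            raw_spec = dict(meta["spec"])
            raw_spec["hidden"] = tuple(raw_spec["hidden"])
            spec = TransitionModelSpec(**raw_spec)
            model = cls(spec)
            n = len(spec.layer_sizes) - 1
            model.net.set_weights([data[f"w{i}"] for i in range(2 * n)])
            model.fitted = bool(meta["fitted"])
        return model


class TransitionEnsemble:
    """Average of independently seeded transition models (same interface)."""

    def __init__(self, members: list[TransitionModel]):
        if not members:
            raise ArgumentError("ensemble needs at least one member")
        self.members = members
        self.spec = members[0].spec
        self.feature_hash = members[0].feature_hash

    @property
    def fitted(self) -> bool:
        return all(m.fitted for m in self.members)

    def predict(self, states: np.ndarray, actions: np.ndarray) -> TransitionPrediction:
        preds = [m.predict(states, actions) for m in self.members]
        return TransitionPrediction(
            event_prob=np.mean([p.event_prob for p in preds], axis=0),
            ed_given_event=np.mean([p.ed_given_event for p in preds], axis=0),
            need_probs=np.mean([p.need_probs for p in preds], axis=0),
            continuous=np.mean([p.continuous for p in preds], axis=0),
        )

    def event_probability(self, states: np.ndarray, actions: np.ndarray) -> np.ndarray:
        return self.predict(states, actions).event_prob

    def save(self, path) -> None:
        meta = {
            "kind": "transition_ensemble",
            "n_members": len(self.members),
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in asdict_spec(self.spec).items()},
            "feature_hash": self.feature_hash,
            "fitted": self.fitted,
        }
        arrays = {}
        for m, member in enumerate(self.members):
            for i, w in enumerate(member.net.get_weights()):
                arrays[f"m{m}_w{i}"] = w
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TransitionEnsemble":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["feature_hash"] != state_dictionary_hash():
                raise ChecksumMismatchError(
                    "checkpoint was trained under a different state-feature dictionary"
                )
            raw_spec = dict(meta["spec"])
            raw_spec["hidden"] = tuple(raw_spec["hidden"])
            spec = TransitionModelSpec(**raw_spec)
            members = []
            n_weights = 2 * (len(spec.layer_sizes) - 1)
            for m in range(meta["n_members"]):
                member = TransitionModel(spec)
                member.net.set_weights([data[f"m{m}_w{i}"] for i in range(n_weights)])
                member.fitted = bool(meta["fitted"])
                members.append(member)
        return cls(members)


def load_transition_checkpoint(path):
    """Load either a single transition model or an ensemble checkpoint."""
    with np.load(path, allow_pickle=False) as data:
        kind = json.loads(str(data["meta"]))["kind"]
    if kind == "transition_ensemble":
        return TransitionEnsemble.load(path)
    return TransitionModel.load(path)


def fit_transition_model(
    trajectories: TrajectoryBatch,
    spec: TransitionModelSpec = TransitionModelSpec(),
    seed: int = 42,
) -> TransitionModel | TransitionEnsemble:
    """Fit the transition dynamics on logged trajectories (seeded).

    With ``spec.ensemble_members > 1``, fits that many independently seeded
    members (seeds ``seed, seed+1, ...``) and returns their averaging
    ensemble.
    """
    if spec.ensemble_members < 1:
        raise ArgumentError("ensemble_members must be >= 1")
    if spec.ensemble_members == 1:
        return TransitionModel(spec, seed=seed).fit(trajectories)
    members = [
        TransitionModel(spec, seed=seed + k).fit(trajectories)
        for k in range(spec.ensemble_members)
    ]
    return TransitionEnsemble(members)


# ---------------------------------------------------------------------------
# Calibration / discrimination diagnostics


@dataclass(frozen=True)
class CalibrationReport:
    """Probability-model diagnostics for the event head."""

    ece: float
    auc: float
    brier: float
    calibration_slope: float
    hl_statistic: float
    hl_pvalue: float
    n: int

    def to_dict(self) -> dict:
        return {
            "ece": self.ece,
            "auc": self.auc,
            "brier": self.brier,
            "calibration_slope": self.calibration_slope,
            "hl_statistic": self.hl_statistic,
            "hl_pvalue": self.hl_pvalue,
            "n": self.n,
        }


def expected_calibration_error(pred: np.ndarray, obs: np.ndarray, n_bins: int = 10) -> float:
    """Bin-weighted mean absolute gap between predicted probability and
    observed frequency, over ``n_bins`` equal-width bins of [0, 1]."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pred, edges[1:-1]), 0, n_bins - 1)
    ece = 0.0
    for b in range(n_bins):
        sel = which == b
        nb = int(sel.sum())
        if nb:
            ece += (nb / pred.size) * abs(pred[sel].mean() - obs[sel].mean())
    return float(ece)


def auc_score(pred: np.ndarray, obs: np.ndarray) -> float:
    """AUC via the Mann–Whitney rank statistic; tied predictions get half credit."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=int)
    n1 = int(obs.sum())
    n0 = obs.size - n1
    if n1 == 0 or n0 == 0:
        raise ArgumentError("AUC undefined: only one outcome class present")
    ranks = rankdata(pred)
    return float((ranks[obs == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def calibration_slope(pred: np.ndarray, obs: np.ndarray) -> float:
    """Slope from an ML logistic regression of outcomes on logit(pred)."""
    import statsmodels.api as sm

    p = np.clip(np.asarray(pred, dtype=float), 1e-6, 1.0 - 1e-6)
    logit = np.log(p / (1.0 - p))
    X = sm.add_constant(logit)
    fit = sm.GLM(np.asarray(obs, dtype=float), X,
                 family=sm.families.Binomial()).fit()
    return float(fit.params[1])


def hosmer_lemeshow(pred: np.ndarray, obs: np.ndarray, groups: int = 10) -> tuple[float, float]:
    """Hosmer–Lemeshow statistic and p-value over equal-frequency groups."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    order = np.argsort(pred, kind="stable")
    splits = np.array_split(order, groups)
    stat = 0.0
    used = 0
    for grp in splits:
        if grp.size == 0:
            continue
        e1 = pred[grp].sum()
        o1 = obs[grp].sum()
        e0 = grp.size - e1
        o0 = grp.size - o1
        if e1 > 0 and e0 > 0:
            stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
            used += 1
    df = max(used - 2, 1)
    return float(stat), float(stats.chi2.sf(stat, df))


def calibration_report(
    pred: np.ndarray,
    obs: np.ndarray,
    n_bins: int = 10,
    hl_groups: int = 10,
) -> CalibrationReport:
    """Full calibration and discrimination report for predicted event
    probabilities against observed binary events."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ArgumentError("predictions and outcomes must have equal length")
    if pred.size == 0:
        raise ArgumentError("empty probability vector")
    if (pred < 0).any() or (pred > 1).any():
        raise ArgumentError("probabilities must lie in [0, 1]")
    hl_stat, hl_p = hosmer_lemeshow(pred, obs, hl_groups)
    return CalibrationReport(
        ece=expected_calibration_error(pred, obs, n_bins),
        auc=auc_score(pred, obs.astype(int)),
        brier=float(np.mean((pred - obs) ** 2)),
        calibration_slope=calibration_slope(pred, obs),
        hl_statistic=hl_stat,
        hl_pvalue=hl_p,
        n=pred.size,
    )
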