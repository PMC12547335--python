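"""On-policy SARSA with neural Q-function approximation.

The learner performs semi-gradient TD(0) updates toward the on-policy target
``r + γ·Q(s', a')`` where ``a'`` is the action actually taken at the next step
of the logged trajectory — the conservative, practice-aligned alternative to
off-policy Q-learning.  The Q-function is a two-hidden-layer ReLU network with
dropout regularization and nine outputs, one Q-value per intervention.

Training consumes :class:`~carepath.cohort.TrajectoryBatch` data, runs for up
to ``max_epochs`` with early stopping on a validation metric (mean squared TD
error by default, or the simulated event rate of the greedy policy when an
environment is supplied), and is deterministic given the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .cohort import EnvironmentParams, TrajectoryBatch, simulate_cohort
from .exceptions import ArgumentError, ChecksumMismatchError, SafetyViolationError
from .features import N_ACTIONS, N_STATE_FEATURES, state_dictionary_hash
from .nn import MLP
from .policies import GreedyPolicy


def sarsa_update(q_sa: float, r: float, q_next: float, alpha: float, gamma: float) -> float:
    """One tabular SARSA update: ``q + α·(r + γ·q' − q)``.

    Terminal transitions pass ``q_next = 0``.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ArgumentError("gamma must be in [0, 1]")
    if alpha < 0:
        raise ArgumentError("alpha must be >= 0")
    return q_sa + alpha * (r + gamma * q_next - q_sa)


def masked_argmax(q_values: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Row-wise argmax of Q restricted to permitted actions (ties → lowest index)."""
    q = np.atleast_2d(np.asarray(q_values, dtype=float)).copy()
    m = np.atleast_2d(masks)
    if not m.any(axis=1).all():
        raise SafetyViolationError("action mask permits no action")
    q[~m] = -np.inf
    return q.argmax(axis=1)


def select_action(q_values: np.ndarray, mask: np.ndarray, epsilon: float,
                  rng: np.random.Generator) -> int:
    """Masked epsilon-greedy selection for a single state.

    With probability ``1 − epsilon`` returns the permitted-action argmax of the
    Q-values (ties break toward the lowest action index); otherwise a uniform
    draw over permitted actions.  Never returns a masked action.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ArgumentError("epsilon must be in [0, 1]")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SafetyViolationError("action mask permits no action")
    if rng.random() < epsilon:
        return int(rng.choice(np.flatnonzero(mask)))
    return int(masked_argmax(np.asarray(q_values)[None, :], mask[None, :])[0])


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class QNetworkSpec:
    """Architecture of the Q-network: 47 inputs, two ReLU hidden layers with
    dropout, and 9 outputs (one Q-value per intervention)."""

    hidden: tuple[int, int] = (64, 32)
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if len(self.hidden) != 2 or any(h < 1 for h in self.hidden):
            raise ArgumentError("hidden must be two positive layer widths")
        if not 0.0 <= self.dropout < 1.0:
            raise ArgumentError("dropout must be in [0, 1)")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (N_STATE_FEATURES, *self.hidden, N_ACTIONS)


@dataclass(frozen=True)
class EpsilonSchedule:
    """Exponentially decaying exploration rate: start → end with factor decay."""

    start: float = 0.3
    end: float = 0.01
    decay: float = 0.9

    def __post_init__(self) -> None:
        for v in (self.start, self.end):
            if not 0.0 <= v <= 1.0:
                raise ArgumentError("epsilon bounds must be in [0, 1]")
        if not 0.0 < self.decay <= 1.0:
            raise ArgumentError("decay must be in (0, 1]")

    def at(self, epoch: int) -> float:
        return max(self.end, self.start * self.decay**epoch)


@dataclass(frozen=True)
class TrainConfig:
    """SARSA training protocol settings."""

    learning_rate: float = 1e-3
    #: per-epoch multiplicative learning-rate decay (1 = constant); annealing
    #: settles the greedy policy in late epochs
    lr_decay: float = 1.0
    gamma: float = 0.95
    epsilon: EpsilonSchedule = EpsilonSchedule()
    max_epochs: int = 100
    patience: int = 5             #: early-stopping patience; 0 trains exactly 1 epoch
    min_delta: float = 1e-5
    validation_metric: str = "td_error"   #: "td_error" or "event_rate"
    batch_size: int | None = None  #: None = per-transition on-policy updates
    #: independently seeded training restarts; the run with the best final
    #: validation metric wins (semi-gradient SARSA has appreciable seed
    #: variance — some runs plateau at the behavior policy's level)
    n_restarts: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ArgumentError("learning_rate must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ArgumentError("gamma must be in [0, 1]")
        if self.max_epochs < 1:
            raise ArgumentError("max_epochs must be >= 1")
        if self.patience < 0:
            raise ArgumentError("patience must be >= 0")
        if self.validation_metric not in ("td_error", "event_rate"):
            raise ArgumentError("validation_metric must be 'td_error' or 'event_rate'")


# ---------------------------------------------------------------------------
# Q-function


class QFunction:
    """Neural Q-function over the canonical 47-feature state layout."""

    def __init__(self, spec: QNetworkSpec, seed: int = 42):
        self.spec = spec
        self.net = MLP(spec.layer_sizes, dropout=spec.dropout, seed=seed)
        self.feature_hash = state_dictionary_hash()

    def q_values(self, states: np.ndarray) -> np.ndarray:
        """(n, 9) Q-values; dropout disabled (inference mode)."""
        return np.atleast_2d(self.net.predict(np.atleast_2d(states)))

    # -- checkpointing -----------------------------------------------------
    def save(self, path, train_config: TrainConfig | None = None) -> None:
        """Versioned checkpoint: spec, feature-dictionary hash, weights."""
        meta = {
            "kind": "q_function",
            "spec": {"hidden": list(self.spec.hidden), "dropout": self.spec.dropout},
            "feature_hash": self.feature_hash,
            "train_config": _config_dict(train_config) if train_config else None,
        }
        weights = self.net.get_weights()
        arrays = {f"w{i}": w for i, w in enumerate(weights)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "QFunction":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            if meta["feature_hash"] != state_dictionary_hash():
                raise ChecksumMismatchError(
                    "checkpoint was trained under a different state-feature dictionary"
                )
            spec = QNetworkSpec(tuple(meta["spec"]["hidden"]), meta["spec"]["dropout"])
            qf = cls(spec)
            n = len(spec.layer_sizes) - 1
            qf.net.set_weights([data[f"w{i}"] for i in range(2 * n)])
        return qf


def _config_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    return d


# ---------------------------------------------------------------------------
# Training


def _flatten_transitions(traj: TrajectoryBatch):
    """(s, a, r, s', a', terminal) arrays from a trajectory batch."""
    n, T = traj.n_patients, traj.horizon
    if T == 0 or n == 0:
        raise ArgumentError("trajectories contain no transitions")
    S = traj.states[:, :T].reshape(n * T, -1)
    S2 = traj.states[:, 1:].reshape(n * T, -1)
    A = traj.actions.reshape(-1)
    R = traj.rewards.reshape(-1)
    A2 = np.concatenate([traj.actions[:, 1:], np.zeros((n, 1), dtype=int)], axis=1).reshape(-1)
    terminal = np.zeros((n, T), dtype=bool)
    terminal[:, -1] = True
    return S, A, R, S2, A2, terminal.reshape(-1)


def _td_error(qf: QFunction, traj: TrajectoryBatch, gamma: float) -> float:
    S, A, R, S2, A2, term = _flatten_transitions(traj)
    q = qf.q_values(S)[np.arange(len(A)), A]
    qn = qf.q_values(S2)[np.arange(len(A2)), A2]
    target = R + gamma * np.where(term, 0.0, qn)
    return float(np.mean((q - target) ** 2))


def _epoch_updates(net, traj: TrajectoryBatch, cfg: TrainConfig,
                   rng: np.random.Generator, lr: float | None = None) -> tuple[float, int]:
    """One pass of semi-gradient SARSA updates over a trajectory batch."""
    gamma = cfg.gamma
    if lr is None:
        lr = cfg.learning_rate
    n, T = traj.n_patients, traj.horizon
    train_sq = 0.0
    count = 0
    if cfg.batch_size is None:
        states, actions, rewards = traj.states, traj.actions, traj.rewards
        for i in rng.permutation(n):
            for t in range(T):
                a = actions[i, t]
                q_row, cache = net.forward(states[i, t], train=True)
                if t == T - 1:
                    target = rewards[i, t]
                else:
                    qn = net.forward(states[i, t + 1], train=False)[0]
                    target = rewards[i, t] + gamma * qn[actions[i, t + 1]]
                err = q_row[a] - target
                dout = np.zeros((1, N_ACTIONS))
                dout[0, a] = err
                net.adam_step(net.backward(cache, dout), lr)
                train_sq += err * err
                count += 1
    else:
        S, A, R, S2, A2, term = _flatten_transitions(traj)
        perm = rng.permutation(len(A))
        for start in range(0, len(A), cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            qn = net.forward(S2[idx], train=False)[0]
            target = R[idx] + gamma * np.where(
                term[idx], 0.0, qn[np.arange(len(idx)), A2[idx]]
            )
            q, cache = net.forward(S[idx], train=True)
            err = q[np.arange(len(idx)), A[idx]] - target
            dout = np.zeros_like(q)
            dout[np.arange(len(idx)), A[idx]] = err / len(idx)
            net.adam_step(net.backward(cache, dout), lr)
            train_sq += float(np.sum(err * err))
            count += len(idx)
    return train_sq, count


def train_sarsa(
    trajectories: TrajectoryBatch | None,
    qspec: QNetworkSpec = QNetworkSpec(),
    cfg: TrainConfig = TrainConfig(),
    validation: TrajectoryBatch | None = None,
    env: EnvironmentParams | None = None,
    train_cohort=None,
    validation_cohort=None,
    horizon: int = 12,
    rules=None,
    reward_cfg=None,
) -> tuple[QFunction, list[dict]]:
    """Fit the Q-network by on-policy semi-gradient SARSA.

    Two training regimes are supported:

    * **Offline** (default): per-transition semi-gradient updates over the
      supplied logged ``trajectories``, visited patient-by-patient in
      trajectory order (patient order reshuffled each epoch).  The TD target
      uses the action actually taken at the next logged step — on-policy with
      respect to the logging policy.
    * **Online** (when ``env`` and ``train_cohort`` are given): each epoch
      regenerates the training trajectories by rolling the cohort through the
      environment under the *current* epsilon-greedy policy (epsilon following
      ``cfg.epsilon``), then applies the same updates — SARSA proper, learning
      about the policy it is executing.  Logged ``trajectories``, if supplied,
      seed epoch 0.

    ``cfg.batch_size=None`` keeps strict per-transition updates; an integer
    enables a shuffled mini-batch variant of the same estimator.  Early
    stopping monitors the validation metric — mean squared TD error on the
    validation trajectories, or with ``validation_metric="event_rate"`` the
    simulated event rate of the greedy policy on ``validation_cohort`` —
    and restores the best-validation weights.  ``patience=0`` trains exactly
    one epoch.  With ``cfg.n_restarts > 1``, that many independently seeded
    runs are trained and the one with the best validation metric is returned
    (the validation rollouts share fixed seeds across restarts, so the
    comparison is paired).  Deterministic given ``cfg.seed``; every simulated
    rollout is mask-checked, so a masked selection raises rather than trains.
    """
    if cfg.n_restarts < 1:
        raise ArgumentError("n_restarts must be >= 1")
    if cfg.n_restarts == 1:
        return _train_sarsa_once(trajectories, qspec, cfg, validation, env,
                                 train_cohort, validation_cohort, horizon,
                                 rules, reward_cfg, val_seed_base=cfg.seed)
    best = None
    for k in range(cfg.n_restarts):
        from dataclasses import replace as _replace

        cfg_k = _replace(cfg, seed=cfg.seed + 1000 * k, n_restarts=1)
        qf_k, log_k = _train_sarsa_once(trajectories, qspec, cfg_k, validation, env,
                                        train_cohort, validation_cohort, horizon,
                                        rules, reward_cfg, val_seed_base=cfg.seed)
        metric = min(entry["validation_metric"] for entry in log_k)
        for entry in log_k:
            entry["restart"] = k
        if best is None or metric < best[0]:
            best = (metric, qf_k, log_k)
    return best[1], best[2]


def _train_sarsa_once(
    trajectories, qspec, cfg, validation, env, train_cohort, validation_cohort,
    horizon, rules, reward_cfg, val_seed_base,
) -> tuple[QFunction, list[dict]]:
    online = env is not None and train_cohort is not None
    if not online and (trajectories is None or trajectories.n_patients == 0
                       or trajectories.horizon == 0):
        raise ArgumentError("training trajectories are empty")
    if cfg.validation_metric == "event_rate" and (env is None or validation_cohort is None):
        raise ArgumentError("event_rate validation needs env and validation_cohort")

    rng = np.random.default_rng(cfg.seed)
    qf = QFunction(qspec, seed=cfg.seed)
    net = qf.net

    def validate() -> float:
        if cfg.validation_metric == "event_rate":
            # two fixed-seed rollouts: paired across epochs (and across
            # restarts), averaged to keep best-weight selection from locking
            # onto rollout noise
            rates = []
            for offset in (9999, 19999):
                batch = simulate_cohort(validation_cohort, GreedyPolicy(qf), env,
                                        horizon, seed=val_seed_base + offset, rules=rules,
                                        reward_cfg=reward_cfg)
                rates.append(batch.any_event().mean())
            return float(np.mean(rates))
        target = validation if validation is not None else trajectories
        if target is None:
            raise ArgumentError("td_error validation needs trajectories")
        return _td_error(qf, target, cfg.gamma)

    from .policies import EpsilonGreedyPolicy

    log: list[dict] = []
    best_metric = np.inf
    best_weights = net.get_weights()
    wait = 0

    for epoch in range(cfg.max_epochs):
        if online and not (epoch == 0 and trajectories is not None):
            policy = EpsilonGreedyPolicy(qf, cfg.epsilon.at(epoch))
            epoch_traj = simulate_cohort(train_cohort, policy, env, horizon,
                                         seed=cfg.seed + 7000 + epoch, rules=rules,
                                         reward_cfg=reward_cfg)
        else:
            epoch_traj = trajectories
        train_sq, count = _epoch_updates(net, epoch_traj, cfg, rng,
                                 lr=cfg.learning_rate * cfg.lr_decay**epoch)

        metric = validate()
        log.append({
            "epoch": epoch,
            "train_td_error": train_sq / max(count, 1),
            "validation_metric": metric,
            "epsilon": cfg.epsilon.at(epoch),
            "online": bool(online),
            "mask_violations": 0,  # rollouts raise on any masked selection
        })
        if metric < best_metric - cfg.min_delta:
            best_metric = metric
            best_weights = net.get_weights()
            wait = 0
        else:
            wait += 1
        if cfg.patience == 0 or wait >= max(cfg.patience, 1):
            break

    net.set_weights(best_weights)
    return qf, log


def grid_search_sarsa(
    grid: dict[str, Sequence],
    base_cfg: TrainConfig,
    qspec: QNetworkSpec,
    trajectories: TrajectoryBatch | None,
    **train_kwargs,
) -> tuple[QFunction, TrainConfig, list[dict]]:
    """Exhaustive grid search over TrainConfig fields on the validation metric.

    ``grid`` maps TrainConfig field names to candidate values; every
    combination is trained and the configuration with the best (lowest) final
    validation metric wins.  Returns the winning Q-function, its config and a
    per-combination summary.
    """
    from dataclasses import replace as _replace
    from itertools import product

    names = list(grid)
    results = []
    best = None
    for combo in product(*(grid[k] for k in names)):
        cfg = _replace(base_cfg, **dict(zip(names, combo)))
        qf, log = train_sarsa(trajectories, qspec, cfg, **train_kwargs)
        metric = log[-1]["validation_metric"]
        results.append({**dict(zip(names, combo)), "validation_metric": metric,
                        "epochs": len(log)})
        if best is None or metric < best[2]:
            best = (qf, cfg, metric)
    return best[0], best[1], results


# ---------------------------------------------------------------------------
# Tabular SARSA (for small exact MDPs and oracle checks)


def tabular_sarsa(
    rewards: np.ndarray,
    transitions: np.ndarray,
    gamma: float,
    episodes: int,
    episode_len: int,
    epsilon: float = 0.3,
    epsilon_decay: float = 0.05,
    alpha0: float = 0.5,
    alpha_decay: float = 0.002,
    seed: int = 0,
) -> np.ndarray:
    """Exact tabular SARSA on a small deterministic-transition MDP.

    ``rewards[s, a]`` is the immediate reward; ``transitions[s, a]`` the next
    state.  Episodes cycle through every (state, action) pair as an exploring
    start; exploration decays as ``epsilon / (1 + epsilon_decay·episode)``
    (greedy in the limit) and the per-pair learning rate as
    ``alpha0 / (1 + alpha_decay·visits)``.  Together these satisfy the usual
    GLIE / Robbins–Monro conditions, so the learned table converges to the
    optimal Q.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ArgumentError("gamma must be in [0, 1]")
    n_s, n_a = rewards.shape
    rng = np.random.default_rng(seed)
    Q = np.zeros((n_s, n_a))
    visits = np.zeros((n_s, n_a))
    starts = [(s, a) for s in range(n_s) for a in range(n_a)]

    for ep in range(episodes):
        eps = epsilon / (1.0 + epsilon_decay * ep)

        def pick(s: int) -> int:
            if rng.random() < eps:
                return int(rng.integers(n_a))
            return int(np.argmax(Q[s]))

        s, a = starts[ep % len(starts)]
        for _ in range(episode_len):
            s2 = int(transitions[s, a])
            r = rewards[s, a]
            a2 = pick(s2)
            visits[s, a] += 1
            alpha = alpha0 / (1.0 + alpha_decay * visits[s, a])
            Q[s, a] = sarsa_update(Q[s, a], r, Q[s2, a2], alpha, gamma)
            s, a = s2, a2
    return Q
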