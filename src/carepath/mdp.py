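"""Action masking, reward shaping and risk-domain logic.

The recommender chooses one of nine mutually exclusive interventions per
monthly decision point.  Clinical appropriateness is enforced two ways:

* a hard **action mask** removes interventions that violate constraint rules
  given the current patient state (watchful waiting is never masked, so the
  permitted set is never empty), and
* a shaped **reward** combining an acute-care-event penalty, a continuous
  risk-reduction signal, a prevention bonus scaled by preintervention risk, an
  intervention-matching bonus, and a safety penalty for masked actions.

Constraint rules ship as editable YAML data (``carepath/data/constraint_rules.yaml``)
rather than code, so deployments can adapt them without touching the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .exceptions import ArgumentError
from .features import (
    ACTION_DOMAIN,
    ACTIONS,
    DOMAIN_FLAGS,
    DOMAINS,
    N_ACTIONS,
    N_STATE_FEATURES,
    NEED_INDICATORS,
    WATCHFUL_WAITING,
    action_index,
    feature_index,
)

_OPS = {
    "ge": np.greater_equal,
    "le": np.less_equal,
    "eq": np.equal,
    "gt": np.greater,
    "lt": np.less,
}


@dataclass(frozen=True)
class MaskRule:
    """Permit ``action`` only when at least one requirement holds.

    ``requires_any`` is a list of ``(feature, op, value)`` predicates over named
    state features; the action is masked out when every predicate is false.
    """

    action: str
    requires_any: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        action_index(self.action)  # validates the name
        for feat, op, _ in self.requires_any:
            feature_index(feat)
            if op not in _OPS:
                raise ArgumentError(f"unknown predicate operator {op!r}")

    def permits(self, states: np.ndarray) -> np.ndarray:
        """Boolean vector: rule satisfied for each row of ``states``."""
        ok = np.zeros(states.shape[0], dtype=bool)
        for feat, op, value in self.requires_any:
            ok |= _OPS[op](states[:, feature_index(feat)], value)
        return ok


def load_rules(path=None) -> list[MaskRule]:
    """Load constraint rules from YAML (the packaged defaults when path=None)."""
    if path is None:
        text = resources.files("carepath").joinpath("data/constraint_rules.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text) or []
    rules = []
    for item in raw:
        reqs = tuple((r["feature"], r["op"], float(r["value"])) for r in item["requires_any"])
        rules.append(MaskRule(action=item["action"], requires_any=reqs))
    return rules


_DEFAULT_RULES: list[MaskRule] | None = None


def default_rules() -> list[MaskRule]:
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_rules()
    return _DEFAULT_RULES


def compute_mask(state: np.ndarray, rules: Sequence[MaskRule] | None = None) -> np.ndarray:
    """Action mask (length 9, True = permitted) for a single state vector.

    Watchful waiting is always permitted, guaranteeing a non-empty mask.  With
    an empty rule list every action is permitted.
    """
    return compute_masks(np.asarray(state, dtype=float)[None, :], rules)[0]


def compute_masks(states: np.ndarray, rules: Sequence[MaskRule] | None = None) -> np.ndarray:
    """Vectorized mask computation: (n, 47) states -> (n, 9) boolean mask."""
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[1] != N_STATE_FEATURES:
        raise ArgumentError(f"states must be (n, {N_STATE_FEATURES})")
    if rules is None:
        rules = default_rules()
    mask = np.ones((states.shape[0], N_ACTIONS), dtype=bool)
    for rule in rules:
        mask[:, action_index(rule.action)] &= rule.permits(states)
    mask[:, WATCHFUL_WAITING] = True
    return mask


# ---------------------------------------------------------------------------
# Risk domains


_DOMAIN_FLAG_IDX = {
    d: np.array([feature_index(f) for f in DOMAIN_FLAGS[d]]) for d in DOMAINS
}
_NEED_IDX = {d: feature_index(NEED_INDICATORS[d]) for d in DOMAINS}

#: Weight of the latent active-need indicator relative to a single raw flag.
#: Larger than the maximum per-domain flag count (5), so an active need always
#: dominates the domain score and the matching bonus targets the active need.
NEED_WEIGHT = 6.0


def domain_scores(states: np.ndarray) -> np.ndarray:
    """Weighted active-need score per domain, shape (n, 3) in DOMAINS order."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    scores = np.empty((states.shape[0], len(DOMAINS)))
    for j, d in enumerate(DOMAINS):
        scores[:, j] = states[:, _DOMAIN_FLAG_IDX[d]].sum(axis=1)
        scores[:, j] += NEED_WEIGHT * states[:, _NEED_IDX[d]]
    return scores


def primary_risk_domains(states: np.ndarray) -> np.ndarray:
    """Primary risk domain index per row (0=medical, 1=behavioral, 2=social).

    Ties break deterministically in the order medical > behavioral > social
    (argmax returns the first maximum).
    """
    return np.argmax(domain_scores(states), axis=1)


def primary_risk_domain(state: np.ndarray) -> str:
    """Domain name with the largest weighted active-need score for one state."""
    return DOMAINS[int(primary_risk_domains(np.asarray(state)[None, :])[0])]


_ACTION_DOMAIN_IDX = np.array(
    [DOMAINS.index(ACTION_DOMAIN[a]) if ACTION_DOMAIN[a] is not None else -1 for a in ACTIONS]
)


def actions_match_domain(states: np.ndarray, actions: np.ndarray) -> np.ndarray:
    """True where each action's domain equals the state's primary risk domain."""
    actions = np.asarray(actions)
    return _ACTION_DOMAIN_IDX[actions] == primary_risk_domains(states)


# ---------------------------------------------------------------------------
# Reward


@dataclass(frozen=True)
class RewardConfig:
    """Weights of the multi-component clinical reward.

    Defaults keep the acute-event penalty larger in magnitude than the sum of
    any single step's bonuses (|w_event| > w_prev + w_match), so no stack of
    bonuses can outweigh causing an event.
    """

    w_event: float = -1.0   #: penalty per acute care event (< 0)
    w_risk: float = 0.5     #: coefficient on (risk_before - risk_after) (> 0)
    w_prev: float = 0.5     #: prevention bonus coefficient, scaled by preintervention risk (> 0)
    w_match: float = 0.25   #: bonus when the action matches the primary risk domain (> 0)
    w_safe: float = -1.0    #: safety penalty for a masked action (< 0)

    def __post_init__(self) -> None:
        if not self.w_event < 0:
            raise ArgumentError("w_event must be negative")
        if not self.w_risk > 0:
            raise ArgumentError("w_risk must be positive")
        if not self.w_prev > 0:
            raise ArgumentError("w_prev must be positive")
        if not self.w_match > 0:
            raise ArgumentError("w_match must be positive")
        if not self.w_safe < 0:
            raise ArgumentError("w_safe must be negative")


@dataclass(frozen=True)
class RewardBreakdown:
    """Audited reward components; ``total`` is their exact sum."""

    event_penalty: float
    risk_reduction: float
    prevention_bonus: float
    matching_bonus: float
    safety_penalty: float

    @property
    def total(self) -> float:
        return (
            self.event_penalty
            + self.risk_reduction
            + self.prevention_bonus
            + self.matching_bonus
            + self.safety_penalty
        )


_RISK_IDX = feature_index("risk_score")


def reward_components(
    state: np.ndarray,
    action: int | str,
    next_state: np.ndarray,
    event: bool,
    mask: np.ndarray,
    cfg: RewardConfig = RewardConfig(),
) -> RewardBreakdown:
    """Individually retrievable components of the shaped reward for one step."""
    a = action_index(action) if isinstance(action, str) else int(action)
    state = np.asarray(state, dtype=float)
    next_state = np.asarray(next_state, dtype=float)
    risk_before = float(state[_RISK_IDX])
    risk_after = float(next_state[_RISK_IDX])
    matched = bool(actions_match_domain(state[None, :], np.array([a]))[0])
    masked = not bool(np.asarray(mask)[a])
    return RewardBreakdown(
        event_penalty=cfg.w_event * float(event),
        risk_reduction=cfg.w_risk * (risk_before - risk_after),
        prevention_bonus=cfg.w_prev * risk_before * float(not event),
        matching_bonus=cfg.w_match * float(matched),
        safety_penalty=cfg.w_safe * float(masked),
    )


def compute_reward(
    state: np.ndarray,
    action: int | str,
    next_state: np.ndarray,
    event: bool,
    mask: np.ndarray,
    cfg: RewardConfig = RewardConfig(),
) -> float:
    """Scalar shaped reward (the exact sum of :func:`reward_components`)."""
    return reward_components(state, action, next_state, event, mask, cfg).total


def compute_rewards(
    states: np.ndarray,
    actions: np.ndarray,
    next_states: np.ndarray,
    events: np.ndarray,
    masked_flags: np.ndarray | None,
    cfg: RewardConfig = RewardConfig(),
) -> np.ndarray:
    """Vectorized reward over aligned step arrays (used by the simulator)."""
    risk_before = states[:, _RISK_IDX]
    risk_after = next_states[:, _RISK_IDX]
    matched = actions_match_domain(states, actions)
    r = (
        cfg.w_event * events.astype(float)
        + cfg.w_risk * (risk_before - risk_after)
        + cfg.w_prev * risk_before * (1.0 - events.astype(float))
        + cfg.w_match * matched.astype(float)
    )
    if masked_flags is not None:
        r = r + cfg.w_safe * masked_flags.astype(float)
    return r
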