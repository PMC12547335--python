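"""Intervention policies: status-quo behavior, Q-greedy, epsilon-greedy, replay.

Every policy exposes ``select(states, masks, rng, step=0) -> actions`` over a
batch of patients and is guaranteed never to emit a masked action.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

from .exceptions import ArgumentError
from .features import (
    ACTIONS,
    DOMAINS,
    N_ACTIONS,
    WATCHFUL_WAITING,
    action_index,
    feature_index,
)

_NEED_COLS = [feature_index(f"need_{d}") for d in DOMAINS]
#: action matched to each need domain by the status-quo heuristic
_MEDICAL_ACTION = action_index("chronic_condition_support")
_BEHAVIORAL_ACTION = action_index("mental_health_support")
#: social actions tried in salience order, gated on the corresponding flag
_SOCIAL_CHOICES = (
    ("housing_instability", action_index("housing_assistance")),
    ("food_insecurity", action_index("food_assistance")),
    ("transportation_barriers", action_index("transportation_assistance")),
    ("utility_needs", action_index("utility_assistance")),
)


@runtime_checkable
class Policy(Protocol):
    def select(self, states: np.ndarray, masks: np.ndarray, rng: np.random.Generator,
               step: int = 0) -> np.ndarray: ...


def _masked_categorical(weights: np.ndarray, masks: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-row draw from ``weights`` restricted to permitted actions."""
    w = np.broadcast_to(weights, masks.shape).astype(float) * masks
    totals = w.sum(axis=1, keepdims=True)
    # watchful waiting is always permitted, so a zero row can only arise from
    # zero bias weight on every permitted action — fall back to uniform there
    zero = totals[:, 0] <= 0
    if zero.any():
        w = w.copy()
        w[zero] = masks[zero].astype(float)
        totals = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w / totals, axis=1)
    u = rng.random(masks.shape[0])
    return (cum > u[:, None]).argmax(axis=1)


class BehaviorPolicy:
    """Status-quo care-management heuristic.

    With probability ``match_prob`` the policy addresses the most salient
    observed need: chronic-condition support for an active medical need,
    mental-health support for a behavioral need (mirroring observed practice,
    which defaults to mental-health framing even when substance use is the
    driver), and the first flagged social assistance for a social need.
    Otherwise it draws from a biased distribution over permitted actions that
    over-weights mental-health support and watchful waiting.
    """

    def __init__(self, match_prob: float = 0.45,
                 action_bias: np.ndarray | tuple | None = None):
        if not 0.0 <= match_prob <= 1.0:
            raise ArgumentError("match_prob must be in [0, 1]")
        self.match_prob = float(match_prob)
        if action_bias is None:
            from .cohort import DEFAULT_BEHAVIOR_BIAS
            action_bias = DEFAULT_BEHAVIOR_BIAS
        self.action_bias = np.asarray(action_bias, dtype=float)
        if self.action_bias.shape != (N_ACTIONS,) or (self.action_bias < 0).any():
            raise ArgumentError("action_bias must be 9 nonnegative weights")

    @classmethod
    def from_env(cls, env) -> "BehaviorPolicy":
        return cls(env.behavior_match_prob, env.behavior_action_bias)

    def _matched_actions(self, states: np.ndarray) -> np.ndarray:
        """Heuristic matched action per row; -1 where no need is active."""
        need = states[:, _NEED_COLS]
        has = need.sum(axis=1) > 0
        dom = need.argmax(axis=1)
        out = np.full(states.shape[0], -1, dtype=int)
        out[has & (dom == 0)] = _MEDICAL_ACTION
        out[has & (dom == 1)] = _BEHAVIORAL_ACTION
        social = has & (dom == 2)
        chosen = np.full(states.shape[0], -1, dtype=int)
        for flag, act in _SOCIAL_CHOICES:
            col = states[:, feature_index(flag)] > 0
            chosen = np.where((chosen < 0) & col, act, chosen)
        out[social] = chosen[social]
        return out

    def select(self, states, masks, rng, step: int = 0) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        n = states.shape[0]
        matched = self._matched_actions(states)
        use_match = (rng.random(n) < self.match_prob) & (matched >= 0)
        # never emit a masked matched action
        rows = np.arange(n)
        ok = np.zeros(n, dtype=bool)
        valid = matched >= 0
        ok[valid] = masks[rows[valid], matched[valid]]
        use_match &= ok
        fallback = _masked_categorical(self.action_bias, masks, rng)
        return np.where(use_match, matched, fallback)


class GreedyPolicy:
    """Deterministic argmax of the Q-function over permitted actions."""

    def __init__(self, qfunc):
        self.qfunc = qfunc

    def select(self, states, masks, rng, step: int = 0) -> np.ndarray:
        from .sarsa import masked_argmax

        q = self.qfunc.q_values(np.atleast_2d(states))
        return masked_argmax(q, masks)


class EpsilonGreedyPolicy:
    """Masked epsilon-greedy exploration around a Q-function."""

    def __init__(self, qfunc, epsilon: float):
        if not 0.0 <= epsilon <= 1.0:
            raise ArgumentError("epsilon must be in [0, 1]")
        self.qfunc = qfunc
        self.epsilon = float(epsilon)

    def select(self, states, masks, rng, step: int = 0) -> np.ndarray:
        from .sarsa import masked_argmax

        states = np.atleast_2d(states)
        greedy = masked_argmax(self.qfunc.q_values(states), masks)
        explore = rng.random(states.shape[0]) < self.epsilon
        uniform = _masked_categorical(np.ones(N_ACTIONS), masks, rng)
        return np.where(explore, uniform, greedy)


class FixedDomainPolicy:
    """Oracle policy that always (or never) matches the active need domain.

    ``matched=True`` picks an unmasked action in the patient's active need
    domain (watchful waiting when no need is active); ``matched=False`` always
    waits, never matching anything.  Used by directional ground-truth checks.
    """

    _DOMAIN_CHOICES = {
        0: (_MEDICAL_ACTION,),
        1: (_BEHAVIORAL_ACTION, action_index("substance_use_support")),
        2: tuple(a for _, a in _SOCIAL_CHOICES),
    }

    def __init__(self, matched: bool = True):
        self.matched = bool(matched)

    def select(self, states, masks, rng, step: int = 0) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        n = states.shape[0]
        out = np.full(n, WATCHFUL_WAITING, dtype=int)
        if not self.matched:
            return out
        need = states[:, _NEED_COLS]
        has = need.sum(axis=1) > 0
        dom = need.argmax(axis=1)
        rows = np.arange(n)
        for d, choices in self._DOMAIN_CHOICES.items():
            sel = has & (dom == d)
            for act in choices:
                use = sel & (out == WATCHFUL_WAITING) & masks[rows, act]
                out[use] = act
        return out


class ReplayPolicy:
    """Replay a logged action sequence, substituting watchful waiting when the
    logged action is masked in the rolled-out state."""

    def __init__(self, actions: np.ndarray):
        self.actions = np.asarray(actions, dtype=int)
        if self.actions.ndim != 2:
            raise ArgumentError("actions must be (n_patients, horizon)")

    def select(self, states, masks, rng, step: int = 0) -> np.ndarray:
        if step >= self.actions.shape[1]:
            raise ArgumentError(f"no logged actions for step {step}")
        a = self.actions[:, step].copy()
        rows = np.arange(a.shape[0])
        a[~masks[rows, a]] = WATCHFUL_WAITING
        return a
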