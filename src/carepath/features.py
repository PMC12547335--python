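"""Canonical state-feature layout and action space.

Every model, trajectory table and checkpoint in this package agrees on a single
fixed ordering of the 47 patient-state features defined here.  The layout covers
demographics, chronic-condition and social-determinant flags, utilization
history over trailing windows, the calculated risk score, cumulative
intervention-history counts, and the active-need-domain indicators that drive
intervention matching.

The action space is the nine mutually exclusive care-management interventions
(eight active supports plus watchful waiting).  Each active intervention is
assigned to one of three need domains — medical, behavioral or social — used by
the matching bonus and by the ground-truth simulator.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

STATE_DICT_VERSION = "1"

#: Fixed 47-feature order.  Do not reorder: checkpoints store a hash of this
#: list and refuse to score states produced under a different layout.
STATE_FEATURES: tuple[str, ...] = (
    # demographics
    "age_std",
    "female",
    "male",
    "gender_other",
    "race_asian",
    "race_black",
    "race_hispanic",
    "race_white",
    "race_other_multiple",
    # chronic conditions
    "hypertension",
    "depression",
    "diabetes",
    "substance_use_disorder",
    "copd",
    "chf",
    # social determinants
    "housing_instability",
    "food_insecurity",
    "transportation_barriers",
    "utility_needs",
    # auxiliary clinical/social flags
    "child_in_household",
    "sud_screen_positive",
    "dme_flag",
    # utilization history (trailing windows, counts)
    "ed_visits_1m",
    "ed_visits_3m",
    "ed_visits_6m",
    "hosp_1m",
    "hosp_3m",
    "hosp_6m",
    "baseline_ed_flag",
    "baseline_hosp_flag",
    "cum_events",
    "months_since_event",
    "month_index",
    # calculated risk score
    "risk_score",
    # cumulative intervention-history counts (one per action, action order)
    "hx_substance_use_support",
    "hx_mental_health_support",
    "hx_chronic_condition_support",
    "hx_food_assistance",
    "hx_housing_assistance",
    "hx_transportation_assistance",
    "hx_utility_assistance",
    "hx_childcare_assistance",
    "hx_watchful_waiting",
    "steps_since_last_intervention",
    # active-need-domain indicators
    "need_medical",
    "need_behavioral",
    "need_social",
)

N_STATE_FEATURES = len(STATE_FEATURES)
assert N_STATE_FEATURES == 47

#: Nine mutually exclusive interventions, in canonical index order.
ACTIONS: tuple[str, ...] = (
    "substance_use_support",
    "mental_health_support",
    "chronic_condition_support",
    "food_assistance",
    "housing_assistance",
    "transportation_assistance",
    "utility_assistance",
    "childcare_assistance",
    "watchful_waiting",
)

N_ACTIONS = len(ACTIONS)
WATCHFUL_WAITING = ACTIONS.index("watchful_waiting")

DOMAINS: tuple[str, ...] = ("medical", "behavioral", "social")

#: Need domain each active intervention addresses; watchful waiting matches
#: nothing.
ACTION_DOMAIN: dict[str, str | None] = {
    "substance_use_support": "behavioral",
    "mental_health_support": "behavioral",
    "chronic_condition_support": "medical",
    "food_assistance": "social",
    "housing_assistance": "social",
    "transportation_assistance": "social",
    "utility_assistance": "social",
    "childcare_assistance": "social",
    "watchful_waiting": None,
}

#: Flags contributing to each domain's need score (weight 1 each).  The active
#: need-domain indicator for the same domain contributes weight 2, so a latent
#: active need dominates raw flag counts.
DOMAIN_FLAGS: dict[str, tuple[str, ...]] = {
    "medical": ("hypertension", "diabetes", "copd", "chf", "dme_flag"),
    "behavioral": ("depression", "substance_use_disorder", "sud_screen_positive"),
    "social": (
        "housing_instability",
        "food_insecurity",
        "transportation_barriers",
        "utility_needs",
    ),
}

NEED_INDICATORS: dict[str, str] = {
    "medical": "need_medical",
    "behavioral": "need_behavioral",
    "social": "need_social",
}

_INDEX = {name: i for i, name in enumerate(STATE_FEATURES)}


def feature_index(name: str) -> int:
    """Position of ``name`` in the canonical 47-feature order."""
    try:
        return _INDEX[name]
    except KeyError:
        raise KeyError(f"unknown state feature: {name!r}") from None


def action_index(name: str) -> int:
    try:
        return ACTIONS.index(name)
    except ValueError:
        raise KeyError(f"unknown action: {name!r}") from None


def state_dictionary() -> dict:
    """Versioned column dictionary shared by trajectory tables and models."""
    return {
        "version": STATE_DICT_VERSION,
        "features": list(STATE_FEATURES),
        "actions": list(ACTIONS),
    }


def state_dictionary_hash() -> str:
    """SHA-256 digest of the column dictionary (checkpoint compatibility key)."""
    blob = json.dumps(state_dictionary(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def load_packaged_dictionary() -> dict:
    """The column dictionary shipped as package data (should equal the code's)."""
    text = resources.files("carepath").joinpath("data/state_features.json").read_text()
    return json.loads(text)
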