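"""Equalized-odds and outcome-disparity fairness assessment.

The equalized-odds discrepancy between two demographic groups is
``max(|TPR₁ − TPR₂|, |FPR₁ − FPR₂|)``; for more than two groups the package
takes the maximum over all pairs, the most conservative natural extension.
Discrepancies at or below 5% are conventionally considered acceptable.

Because disparities are assessed on observed outcomes rather than predicted
risk scores, the headline fairness number per policy arm is the *outcome
disparity*: the maximum pairwise absolute difference in group event rates
within that arm.  An equalized-odds variant is also provided, treating the
paired rollout's binary benefit indicator (event averted under the SARSA
policy relative to status quo) as the prediction and the status-quo event as
the observed label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ArgumentError, UndefinedRateError

#: equalized-odds discrepancies at or below this value (%) are acceptable
ACCEPTABILITY_THRESHOLD = 5.0
#: groups with fewer members than this are flagged as unstable
SMALL_GROUP_MIN = 25
#: minimum group size for inclusion in the headline pairwise disparity — a
#: group event rate over fewer patients has a standard error of several
#: percentage points and would dominate the maximum by noise alone
DISPARITY_MIN_GROUP = 50


def _rates(counts: tuple[float, float, float, float], group: str) -> tuple[float, float]:
    tp, fn, fp, tn = counts
    if tp + fn <= 0:
        raise UndefinedRateError(f"group {group!r} has no positives: TPR undefined")
    if fp + tn <= 0:
        raise UndefinedRateError(f"group {group!r} has no negatives: FPR undefined")
    return tp / (tp + fn), fp / (fp + tn)


def equalized_odds_discrepancy(
    group_counts: Mapping[str, tuple[float, float, float, float]],
) -> float:
    """Equalized-odds discrepancy (%) from per-group (TP, FN, FP, TN) counts.

    For two groups this is ``100·max(|ΔTPR|, |ΔFPR|)``; for more groups, the
    maximum of the two-group discrepancy over all pairs.
    """
    if len(group_counts) < 2:
        raise ArgumentError("need at least two groups")
    rates = {g: _rates(c, g) for g, c in group_counts.items()}
    names = list(rates)
    worst = 0.0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            tpr_i, fpr_i = rates[names[i]]
            tpr_j, fpr_j = rates[names[j]]
            worst = max(worst, abs(tpr_i - tpr_j), abs(fpr_i - fpr_j))
    return 100.0 * worst


def group_event_rates(
    outcomes: pd.DataFrame, groups: Sequence, arm: str
) -> dict[str, float]:
    """Event rate (%) per demographic group within one policy arm."""
    col = {"statusquo": "event_statusquo", "sarsa": "event_sarsa"}.get(arm)
    if col is None:
        raise ArgumentError("arm must be 'statusquo' or 'sarsa'")
    groups = np.asarray(groups)
    if groups.shape[0] != len(outcomes):
        raise ArgumentError("group labels must align with outcomes")
    ev = outcomes[col].to_numpy(dtype=float)
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        out[str(g)] = 100.0 * float(ev[sel].mean())
    return out


def outcome_disparity(outcomes: pd.DataFrame, groups: Sequence, arm: str) -> float:
    """Max pairwise absolute difference (%) in group event rates within an arm."""
    rates = group_event_rates(outcomes, groups, arm)
    if len(rates) < 2:
        raise ArgumentError("need at least two non-empty groups")
    vals = list(rates.values())
    return float(max(vals) - min(vals))


def disparity_reduction(disp_statusquo: float, disp_sarsa: float) -> tuple[float, float | None]:
    """Absolute and relative reduction in disparity between policies.

    The relative reduction is ``100·(disp_sq − disp_sarsa)/disp_sq``; it is
    undefined (None) when the status-quo disparity is zero.
    """
    if disp_statusquo < 0:
        raise ArgumentError("disparities must be nonnegative")
    absolute = disp_statusquo - disp_sarsa
    if disp_statusquo == 0:
        return absolute, (0.0 if disp_sarsa == 0 else None)
    return absolute, 100.0 * absolute / disp_statusquo


def equalized_odds_from_outcomes(
    outcomes: pd.DataFrame, groups: Sequence
) -> float:
    """Equalized-odds discrepancy (%) using the benefit indicator as prediction.

    Prediction = event averted by the SARSA policy (status-quo event occurred
    but the SARSA event did not); label = the status-quo (observed) event.
    """
    groups = np.asarray(groups)
    label = outcomes["event_statusquo"].to_numpy(dtype=int)
    pred = ((outcomes["event_statusquo"] == 1) & (outcomes["event_sarsa"] == 0)).to_numpy(int)
    counts = {}
    for g in pd.unique(groups):
        sel = groups == g
        y, p = label[sel], pred[sel]
        counts[str(g)] = (
            float(((p == 1) & (y == 1)).sum()),
            float(((p == 0) & (y == 1)).sum()),
            float(((p == 1) & (y == 0)).sum()),
            float(((p == 0) & (y == 0)).sum()),
        )
    return equalized_odds_discrepancy(counts)


@dataclass(frozen=True)
class AttributeFairness:
    """Fairness numbers for one demographic attribute."""

    attribute: str
    rates_statusquo: dict[str, float]
    rates_sarsa: dict[str, float]
    disparity_statusquo: float
    disparity_sarsa: float
    reduction: float
    relative_reduction: float | None
    acceptable_statusquo: bool
    acceptable_sarsa: bool
    small_groups: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "rates_statusquo_pct": self.rates_statusquo,
            "rates_sarsa_pct": self.rates_sarsa,
            "disparity_statusquo_pct": self.disparity_statusquo,
            "disparity_sarsa_pct": self.disparity_sarsa,
            "reduction_pct": self.reduction,
            "relative_reduction_pct": self.relative_reduction,
            "acceptable_statusquo": self.acceptable_statusquo,
            "acceptable_sarsa": self.acceptable_sarsa,
            "small_groups": list(self.small_groups),
        }


def fairness_report(
    outcomes: pd.DataFrame,
    group_labels: Mapping[str, Sequence],
) -> dict[str, AttributeFairness]:
    """Per-attribute fairness assessment across both policy arms.

    ``group_labels`` maps attribute names (e.g. gender, race/ethnicity) to
    per-patient group label sequences.  Groups smaller than
    ``SMALL_GROUP_MIN`` are flagged; groups smaller than
    ``DISPARITY_MIN_GROUP`` are — when at least two adequately sized groups
    remain — excluded from the pairwise disparity maximum, since a handful of
    patients would otherwise dominate the headline number.  Per-group rates
    are always reported; nothing is silently pooled.
    """
    report = {}
    for attr, labels in group_labels.items():
        labels = np.asarray(labels)
        small = tuple(
            str(g) for g in pd.unique(labels) if int((labels == g).sum()) < SMALL_GROUP_MIN
        )
        excluded = tuple(
            str(g) for g in pd.unique(labels)
            if int((labels == g).sum()) < DISPARITY_MIN_GROUP
        )
        adequate = ~np.isin(labels.astype(str), excluded)
        if excluded and len(pd.unique(labels[adequate])) >= 2:
            disparity_outcomes = outcomes[adequate]
            disparity_labels = labels[adequate]
        else:
            disparity_outcomes, disparity_labels = outcomes, labels
        d_sq = outcome_disparity(disparity_outcomes, disparity_labels, "statusquo")
        d_rl = outcome_disparity(disparity_outcomes, disparity_labels, "sarsa")
        absolute, relative = disparity_reduction(d_sq, d_rl)
        report[attr] = AttributeFairness(
            attribute=attr,
            rates_statusquo=group_event_rates(outcomes, labels, "statusquo"),
            rates_sarsa=group_event_rates(outcomes, labels, "sarsa"),
            disparity_statusquo=d_sq,
            disparity_sarsa=d_rl,
            reduction=absolute,
            relative_reduction=relative,
            acceptable_statusquo=d_sq <= ACCEPTABILITY_THRESHOLD,
            acceptable_sarsa=d_rl <= ACCEPTABILITY_THRESHOLD,
            small_groups=small,
        )
    return report
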