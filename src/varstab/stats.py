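"""Evaluation layer: confusion metrics, ROC/AUC, combined rules, t-tests.

Classification treats "pathogenic" as the positive class, with higher
scores (ΔΔG, REVEL) meaning more pathogenic; inverted scorers must be
negated by the caller.  The ROC curve is built over all distinct score
thresholds with tied scores grouped (diagonal segments), so its trapezoidal
area equals the Mann–Whitney pair-concordance probability with ties counted
half.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

log = logging.getLogger(__name__)

POSITIVE_LABEL = "pathogenic"
NEGATIVE_LABEL = "benign"


class StatsError(ValueError):
    """Base class for evaluation-layer errors."""


class EmptyClassError(StatsError):
    """Raised when a label class needed for evaluation is empty."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise StatsError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass
class RocCurve:
    """Points are (false-positive rate, true-positive rate), (0,0) → (1,1)."""

    points: list[tuple[float, float]]
    auc: float
    thresholds: list[float] = field(default_factory=list)


@dataclass
class GroupStats:
    """Per-group summary statistics plus a two-group comparison p-value."""

    groups: dict[str, dict[str, float]]       # group -> n/mean/sd/median/q1/q3
    p_value: Optional[float] = None
    test: Optional[str] = None


def _split_scores(
    scores: Sequence[tuple[float, str]],
) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([v for v, lab in scores if lab == POSITIVE_LABEL], dtype=float)
    neg = np.array([v for v, lab in scores if lab == NEGATIVE_LABEL], dtype=float)
    unknown = {lab for _, lab in scores} - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if unknown:
        raise StatsError(f"unknown labels {sorted(unknown)}; expected "
                         f"{POSITIVE_LABEL!r}/{NEGATIVE_LABEL!r}")
    if len(pos) == 0 or len(neg) == 0:
        raise EmptyClassError("both pathogenic and benign scores are required")
    return pos, neg


def confusion(
    scores: Sequence[tuple[float, str]],
    threshold: float,
    direction: str = "greater",
) -> ConfusionCounts:
    """Confusion counts at one threshold.

    With ``direction='greater'`` (the ΔΔG convention) a value strictly above
    the threshold predicts pathogenic; ``'greater_equal'`` makes the
    threshold itself a positive call (REVEL-style cutoffs).
    """
    if direction not in ("greater", "greater_equal"):
        raise StatsError(f"unknown direction {direction!r}")
    pos, neg = _split_scores(scores)
    if direction == "greater":
        called_pos, called_neg = pos > threshold, neg > threshold
    else:
        called_pos, called_neg = pos >= threshold, neg >= threshold
    return ConfusionCounts(
        tp=int(called_pos.sum()),
        fn=int((~called_pos).sum()),
        fp=int(called_neg.sum()),
        tn=int((~called_neg).sum()),
    )


def metrics(c: ConfusionCounts) -> dict[str, Optional[float]]:
    """Sensitivity, specificity, PPV and NPV; undefined ratios are None."""
    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None
    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn),
        "specificity": ratio(c.tn, c.tn + c.fp),
        "ppv": ratio(c.tp, c.tp + c.fp),
        "npv": ratio(c.tn, c.tn + c.fn),
    }


def roc(scores: Sequence[tuple[float, str]]) -> RocCurve:
    """ROC curve over all distinct thresholds, AUC by trapezoidal rule.

    Tied scores are grouped into single curve steps (diagonal segments), so
    the AUC equals the probability that a random pathogenic score exceeds a
    random benign one, counting ties half.
    """
    pos, neg = _split_scores(scores)
    values = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-values, kind="stable")
    values, labels = values[order], labels[order]
    # one step per distinct value: cumulative counts at group boundaries
    distinct = np.nonzero(np.diff(values))[0]
    boundaries = np.r_[distinct, len(values) - 1]
    cum_tp = np.cumsum(labels)[boundaries]
    cum_fp = np.cumsum(1 - labels)[boundaries]
    tpr = np.r_[0.0, cum_tp / len(pos)]
    fpr = np.r_[0.0, cum_fp / len(neg)]
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    thresholds = [math.inf] + values[boundaries].tolist()
    return RocCurve(points=points, auc=auc, thresholds=thresholds)


def combined_rule(
    ddg: float,
    revel: Optional[float],
    ddg_threshold: float,
    revel_threshold: float = 0.7,
    mode: str = "and",
) -> bool:
    """Combine the stability call with a REVEL cutoff.

    ``and`` (default) calls pathogenic only when the variant is both
    destabilizing (ΔΔG strictly above threshold) and has REVEL at or above
    the cutoff — the conjunction trades sensitivity for PPV.  With a missing
    REVEL score the rule falls back to the ΔΔG call alone.
    """
    if mode not in ("and", "or"):
        raise StatsError(f"unknown combination mode {mode!r}")
    ddg_call = ddg > ddg_threshold
    if revel is None or (isinstance(revel, float) and math.isnan(revel)):
        log.warning("combined_rule: missing REVEL score; using ΔΔG call only")
        return ddg_call
    if not 0.0 <= revel <= 1.0:
        raise StatsError(f"REVEL score {revel} outside [0, 1]")
    revel_call = revel >= revel_threshold
    return (ddg_call and revel_call) if mode == "and" else (ddg_call or revel_call)


def t_test_two_sample(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "student",
) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test: ``(t, df, p)``.

    ``student`` pools the variances (df = n_a + n_b − 2); ``welch`` uses the
    Satterthwaite degrees of freedom and is the safer choice when group
    spreads differ, as ΔΔG group SDs typically do.  Two groups with zero
    spread and equal means give p = 1 by convention.
    """
    if variant not in ("student", "welch"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            df = (len(a) + len(b) - 2) if variant == "student" else float("nan")
            return 0.0, float(df), 1.0
        raise StatsError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def group_summary(
    values_by_group: Mapping[str, Sequence[float]],
    compare: Optional[tuple[str, str]] = None,
    test: str = "student",
) -> GroupStats:
    """Per-group n/mean/SD/median/quartiles and an optional two-group t-test.

    Quartiles use linear interpolation between order statistics (numpy's
    default, "type 7").  ``compare`` names the two groups for the p-value;
    by default the pathogenic and benign groups are compared when both are
    present.
    """
    groups: dict[str, dict[str, float]] = {}
    for name, values in values_by_group.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise StatsError(f"group {name!r} is empty")
        groups[name] = {
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
            "median": float(np.median(v)),
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
        }
    if compare is None and POSITIVE_LABEL in groups and NEGATIVE_LABEL in groups:
        compare = (POSITIVE_LABEL, NEGATIVE_LABEL)
    p_value = None
    if compare is not None:
        g1, g2 = compare
        if g1 not in values_by_group or g2 not in values_by_group:
            raise StatsError(f"cannot compare {compare}: group missing")
        a, b = values_by_group[g1], values_by_group[g2]
        if len(a) >= 2 and len(b) >= 2:
            _, _, p_value = t_test_two_sample(a, b, variant=test)
        else:
            log.warning("group comparison %s skipped: fewer than 2 values", compare)
    return GroupStats(groups=groups, p_value=p_value,
                      test=test if p_value is not None else None)
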