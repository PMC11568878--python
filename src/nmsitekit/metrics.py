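"""Evaluation metrics for binary site classification.

The suite reported throughout the package: accuracy, recall, precision,
Matthews correlation coefficient (MCC), area under the ROC curve, and
F1 score, computed from a thresholded confusion matrix plus a rank-based
AUROC. Degenerate cases (no predicted positives, zero MCC denominator)
are reported as 0 with explicit flags rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from nmsitekit.errors import SingleClassError

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "compute_metrics", "auroc", "mcc_from_counts"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a 2x2 confusion matrix."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """The six-metric evaluation report.

    ``undefined`` lists metrics whose denominator was zero and which were
    reported as the conventional 0.
    """

    acc: float
    recall: float
    precision: float
    mcc: float
    auroc: float
    f1: float
    threshold: float = 0.5
    undefined: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return {
            "ACC": self.acc,
            "Recall": self.recall,
            "PRE": self.precision,
            "MCC": self.mcc,
            "AUROC": self.auroc,
            "F1": self.f1,
        }


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Tally the confusion matrix; a probability >= threshold predicts positive."""
    y = np.asarray(labels)
    p = np.asarray(probabilities)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} probabilities")
    if y.size == 0:
        raise ValueError("empty input")
    pred = p >= threshold
    pos = y == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def mcc_from_counts(c: ConfusionCounts) -> float:
    """MCC from confusion counts; 0 when any marginal is empty."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def auroc(labels, probabilities) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equivalent to trapezoidal integration of TPR against FPR over all
    thresholds; tied scores contribute 1/2.
    """
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUROC requires both classes present")
    ranks = rankdata(p)  # average ranks handle ties
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def compute_metrics(labels, probabilities, threshold: float = 0.5) -> MetricReport:
    """Compute the full six-metric report at a classification threshold."""
    c = confusion(labels, probabilities, threshold=threshold)
    undefined: list[str] = []

    acc = (c.tp + c.tn) / c.n

    if c.tp + c.fn == 0:
        recall = 0.0
        undefined.append("Recall")
    else:
        recall = c.tp / (c.tp + c.fn)

    if c.tp + c.fp == 0:
        precision = 0.0
        undefined.append("PRE")
    else:
        precision = c.tp / (c.tp + c.fp)

    mcc = mcc_from_counts(c)
    if (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn) == 0:
        undefined.append("MCC")

    if precision + recall == 0:
        f1 = 0.0
        undefined.append("F1")
    else:
        f1 = 2 * precision * recall / (precision + recall)

    try:
        auc = auroc(labels, probabilities)
    except SingleClassError:
        auc = 0.0
        undefined.append("AUROC")

    return MetricReport(
        acc=acc,
        recall=recall,
        precision=precision,
        mcc=mcc,
        auroc=auc,
        f1=f1,
        threshold=threshold,
        undefined=tuple(undefined),
    )
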