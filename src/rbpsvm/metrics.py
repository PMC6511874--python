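"""Confusion-matrix statistics, ROC/PR curves and PR-optimal cutoff selection.

Conventions (they matter for reproducibility):

* a protein is called positive iff score >= cutoff;
* AUROC uses the Mann-Whitney convention, ties counted 1/2;
* AUPR uses the non-interpolated step rule sum_i (R_i - R_{i-1}) P_i over
  distinct score cutoffs (linear interpolation would inflate it);
* any ratio with a zero denominator is reported as 0 and flagged;
* the "optimal" operating point is the cutoff maximizing F1 along the PR
  sweep, ties broken toward the higher (more conservative) cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve as _sk_roc_curve,
)

from .exceptions import MetricError


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Curve:
    """Ordered (x, y, cutoff) points plus the area under the curve.

    ROC curves store (fpr, tpr, cutoff); PR curves store (recall, precision,
    cutoff). Points are ordered by decreasing cutoff.
    """

    points: List[Tuple[float, float, float]]
    area: float
    kind: str

    def to_frame(self) -> pd.DataFrame:
        xlab, ylab = ("fpr", "tpr") if self.kind == "roc" else ("recall", "precision")
        return pd.DataFrame(
            [(c, x, y) for x, y, c in self.points], columns=["cutoff", xlab, ylab]
        )


def _as_arrays(scores, labels) -> Tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise MetricError(
            f"scores and labels must be equal-length 1-D: {scores.shape} vs {labels.shape}"
        )
    if not set(np.unique(labels)) <= {0, 1}:
        raise MetricError("labels must be binary 0/1")
    return scores, labels


def confusion(scores, labels, cutoff: float) -> ConfusionCounts:
    """Confusion counts at a cutoff (positive call iff score >= cutoff)."""
    scores, labels = _as_arrays(scores, labels)
    called = scores >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(called & (labels == 1))),
        fp=int(np.sum(called & (labels == 0))),
        tn=int(np.sum(~called & (labels == 0))),
        fn=int(np.sum(~called & (labels == 1))),
    )


def _ratio(num: float, den: float, name: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def scalar_metrics(c: ConfusionCounts) -> Dict[str, object]:
    """Sensitivity, specificity, precision, BACC and MCC from counts.

    BACC = (sensitivity + specificity) / 2;
    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
    Zero-denominator ratios are 0 and listed under ``flags``.
    """
    flags: List[str] = []
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity", flags)
    spec = _ratio(c.tn, c.tn + c.fp, "specificity", flags)
    prec = _ratio(c.tp, c.tp + c.fp, "precision", flags)
    mcc_den = float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = _ratio(
        float(c.tp) * c.tn - float(c.fp) * c.fn, np.sqrt(mcc_den), "mcc", flags
    )
    return {
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "bacc": (sens + spec) / 2.0,
        "mcc": mcc,
        "flags": flags,
    }


def roc(scores, labels) -> Curve:
    """ROC curve over all distinct cutoffs with trapezoid AUROC.

    The area equals the Mann-Whitney statistic: the fraction of
    (positive, negative) pairs ranked concordantly, ties counted 1/2.
    """
    scores, labels = _as_arrays(scores, labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("ROC needs both classes present")
    fpr, tpr, cutoffs = _sk_roc_curve(labels, scores, drop_intermediate=False)
    area = float(roc_auc_score(labels, scores))
    points = [(float(x), float(y), float(c)) for x, y, c in zip(fpr, tpr, cutoffs)]
    return Curve(points=points, area=area, kind="roc")


def pr(scores, labels) -> Curve:
    """Precision-recall curve with step-rule (average-precision) AUPR."""
    scores, labels = _as_arrays(scores, labels)
    if int(np.sum(labels == 1)) == 0:
        raise MetricError("PR curve needs at least one positive example")
    precision, recall, cutoffs = precision_recall_curve(labels, scores)
    area = float(average_precision_score(labels, scores))
    # sklearn orders by increasing cutoff and appends a (recall 0, precision 1)
    # sentinel without a threshold; reorder by decreasing cutoff.
    points = [
        (float(r), float(p), float(c))
        for p, r, c in zip(precision[:-1], recall[:-1], cutoffs)
    ][::-1]
    return Curve(points=points, area=area, kind="pr")


def optimal_cutoff_pr(scores, labels) -> Tuple[float, float]:
    """Cutoff maximizing F1 over the PR sweep; ties go to the higher cutoff."""
    scores, labels = _as_arrays(scores, labels)
    if len(np.unique(labels)) < 2:
        raise MetricError("optimal cutoff needs both classes present")
    best_cutoff, best_f1 = np.inf, -1.0
    for cut in sorted(set(scores.tolist()), reverse=True):
        c = confusion(scores, labels, cut)
        den = 2 * c.tp + c.fp + c.fn
        f1 = 2.0 * c.tp / den if den else 0.0
        if f1 > best_f1:
            best_cutoff, best_f1 = cut, f1
    return float(best_cutoff), float(best_f1)


def evaluation_report(scores, labels, cutoff: float = None) -> Dict[str, object]:
    """One-stop report: curves, areas, and scalar metrics at a cutoff.

    When ``cutoff`` is None the PR-optimal (max-F1) cutoff is used and
    reported alongside.
    """
    roc_curve_ = roc(scores, labels)
    pr_curve_ = pr(scores, labels)
    if cutoff is None:
        cutoff, f1 = optimal_cutoff_pr(scores, labels)
    else:
        c0 = confusion(scores, labels, cutoff)
        den = 2 * c0.tp + c0.fp + c0.fn
        f1 = 2.0 * c0.tp / den if den else 0.0
    counts = confusion(scores, labels, cutoff)
    report: Dict[str, object] = {
        "auroc": roc_curve_.area,
        "aupr": pr_curve_.area,
        "cutoff": float(cutoff),
        "f1": float(f1),
        "counts": counts,
        "roc": roc_curve_,
        "pr": pr_curve_,
    }
    report.update(scalar_metrics(counts))
    return report
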