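"""Classification metric suite: confusion-matrix scalars and ROC/PR curves.

Scalars from a confusion matrix (TP, FP, TN, FN):

    SE  = TP / (TP + FN)                    sensitivity / recall
    SP  = TN / (TN + FP)                    specificity
    PR  = TP / (TP + FP)                    precision
    F1  = 2 * SE * PR / (SE + PR)
    ACC = (TP + TN) / (TP + FP + TN + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

A zero denominator yields 0 and the metric name is recorded in
``EvalReport.undefined`` instead of crashing a degenerate fold.

Curves are computed from continuous scores with scikit-learn: AUC is the
trapezoidal area under the ROC curve (identical to the Mann-Whitney
pair-ranking statistic) and AUPR is the step-wise average-precision sum
(precision at each recall change), which avoids the optimistic bias of
trapezoidal interpolation in PR space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .io import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValidationError("confusion counts sum to zero")


@dataclass
class EvalReport:
    """Scalar metrics plus (optional) ROC and PR curves."""

    se: float
    sp: float
    pr: float
    acc: float
    f1: float
    mcc: float
    auc: float | None = None
    aupr: float | None = None
    roc_points: np.ndarray | None = None  # columns: FPR, TPR, threshold
    pr_points: np.ndarray | None = None  # columns: recall, precision
    counts: ConfusionCounts | None = None
    undefined: list[str] = field(default_factory=list)

    def scalars(self) -> dict[str, float]:
        out = {"SE": self.se, "SP": self.sp, "PR": self.pr, "ACC": self.acc,
               "F1": self.f1, "MCC": self.mcc}
        if self.auc is not None:
            out["AUC"] = self.auc
        if self.aupr is not None:
            out["AUPR"] = self.aupr
        return out


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts) -> EvalReport:
    """Evaluate the six scalar metrics; zero denominators give 0 + a flag."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    undefined: list[str] = []
    se = _ratio(tp, tp + fn, "SE", undefined)
    sp = _ratio(tn, tn + fp, "SP", undefined)
    pr = _ratio(tp, tp + fp, "PR", undefined)
    acc = (tp + tn) / (tp + fp + tn + fn)
    f1 = _ratio(2 * se * pr, se + pr, "F1", undefined)
    mcc_den = math.sqrt(
        float(tp + fn) * float(tn + fp) * float(tp + fp) * float(tn + fn)
    )
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "MCC", undefined)
    return EvalReport(se, sp, pr, acc, f1, mcc, counts=counts, undefined=undefined)


def roc_pr(scores, labels) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ROC and PR curves with their areas from continuous scores.

    Returns ``(roc_points, pr_points, auc, aupr)``. Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise ValidationError("ROC/PR need both classes present")
    fpr, tpr, thr = _skm.roc_curve(labels, scores)
    auc = float(_skm.auc(fpr, tpr))
    prec, rec, _ = _skm.precision_recall_curve(labels, scores)
    aupr = float(_skm.average_precision_score(labels, scores))
    roc_points = np.column_stack([fpr, tpr, thr])
    pr_points = np.column_stack([rec, prec])
    return roc_points, pr_points, auc, aupr


def report_from_scores(scores, labels, threshold: float = 0.0) -> EvalReport:
    """Full report: confusion at ``score > threshold`` plus curves and areas."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores > threshold).astype(int)
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (labels == 1))),
        fp=int(np.sum((pred == 1) & (labels == 0))),
        tn=int(np.sum((pred == 0) & (labels == 0))),
        fn=int(np.sum((pred == 0) & (labels == 1))),
    )
    rep = metrics(counts)
    if len(np.unique(labels)) == 2:
        rep.roc_points, rep.pr_points, rep.auc, rep.aupr = roc_pr(scores, labels)
    return rep


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney pair statistic (independent of any curve).

    Fraction of (positive, negative) pairs ranked concordantly, ties
    counting one half. Quadratic in n; intended as a cross-check.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("need both classes")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)
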