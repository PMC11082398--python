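"""Confusion-matrix metrics, ROC curves, and AUC.

Metrics follow the classic binary definitions

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 * Precision * Recall / (Precision + Recall)

extended to K classes by a one-vs-rest reduction: per-class TP/FP/TN/FN
counts are macro-averaged (unweighted over classes) into a single precision
and recall, accuracy is trace/total, and the reported F1 is the harmonic
mean of the macro precision and macro recall.  Macro averaging makes rare
classes pull precision/recall below accuracy, which is the behaviour these
reports are designed to expose on imbalanced tasks.

ROC curves are computed per class (one-vs-rest) by sweeping the unique
score thresholds; AUC is the trapezoidal area, and the multiclass summary
is the macro average of per-class AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "confusion_matrix",
    "metrics_from_cm",
    "roc_curve_ovr",
    "auc_from_roc",
    "harmonic_f1",
]


@dataclass
class ConfusionMatrix:
    """K x K count matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    """Summary metrics in percent (AUC on [0, 1]) with per-class breakdown."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc_roc: float | None = None
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_roc": self.auc_roc,
        }


def confusion_matrix(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_order: Sequence[str],
) -> ConfusionMatrix:
    """Tally a confusion matrix in the given fixed class order."""
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred have different lengths")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def harmonic_f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units as its inputs)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics_from_cm(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, macro precision/recall, and harmonic-mean F1 (percent).

    Per-class divisions by zero (a class never predicted, or absent from
    the truth) contribute 0 to the macro average and are flagged in the
    per-class breakdown.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    per_class: dict[str, dict[str, float]] = {}
    precisions = np.zeros(len(cm.class_order))
    recalls = np.zeros(len(cm.class_order))
    for i, cls in enumerate(cm.class_order):
        prec = tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] > 0 else 0.0
        rec = tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] > 0 else 0.0
        precisions[i] = prec
        recalls[i] = rec
        per_class[cls] = {
            "precision": 100.0 * prec,
            "recall": 100.0 * rec,
            "f1": 100.0 * harmonic_f1(prec, rec),
            "support": float(tp[i] + fn[i]),
            "undefined_precision": float(tp[i] + fp[i] == 0),
            "undefined_recall": float(tp[i] + fn[i] == 0),
        }
    accuracy = 100.0 * tp.sum() / total
    macro_precision = 100.0 * precisions.mean()
    macro_recall = 100.0 * recalls.mean()
    f1 = harmonic_f1(macro_precision, macro_recall)
    return MetricReport(
        accuracy=accuracy,
        precision=macro_precision,
        recall=macro_recall,
        f1=f1,
        per_class=per_class,
    )


def roc_curve_ovr(
    y_true: Sequence[str],
    class_scores: np.ndarray,
    class_order: Sequence[str],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """One-vs-rest ROC curve per class.

    ``class_scores`` is ``(n_samples, n_classes)`` in ``class_order``
    column order (probabilities or decision values).  Each curve sweeps the
    unique score thresholds from strictest to loosest, running monotonically
    from (0, 0) to (1, 1).  A class absent from ``y_true`` has an undefined
    curve and is omitted from the result.
    """
    scores = np.asarray(class_scores, dtype=float)
    y = np.asarray(y_true)
    if scores.shape != (len(y), len(class_order)):
        raise ValueError(
            f"class_scores shape {scores.shape} does not match "
            f"({len(y)} samples, {len(class_order)} classes)"
        )
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, cls in enumerate(class_order):
        pos = y == cls
        n_pos = int(pos.sum())
        n_neg = len(y) - n_pos
        if n_pos == 0 or n_neg == 0:
            continue
        s = scores[:, j]
        order = np.argsort(-s, kind="stable")
        s_sorted = s[order]
        pos_sorted = pos[order]
        tp_cum = np.cumsum(pos_sorted)
        fp_cum = np.cumsum(~pos_sorted)
        # threshold boundaries: keep only the last point of each tied score run
        distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
        tpr = np.r_[0.0, tp_cum[distinct] / n_pos]
        fpr = np.r_[0.0, fp_cum[distinct] / n_neg]
        curves[cls] = (fpr, tpr)
    return curves


def auc_from_roc(points: tuple[np.ndarray, np.ndarray]) -> float:
    """Trapezoidal area under one ROC curve given as (FPR, TPR) arrays."""
    fpr, tpr = (np.asarray(a, dtype=float) for a in points)
    if fpr.size != tpr.size or fpr.size < 2:
        raise ValueError("an ROC curve needs at least two (FPR, TPR) points")
    return float(np.trapezoid(tpr, fpr))


def macro_auc(
    y_true: Sequence[str],
    class_scores: np.ndarray,
    class_order: Sequence[str],
) -> float:
    """Macro-averaged one-vs-rest AUC over classes present in ``y_true``."""
    curves = roc_curve_ovr(y_true, class_scores, class_order)
    if not curves:
        raise ValueError("no class has both positives and negatives")
    return float(np.mean([auc_from_roc(c) for c in curves.values()]))
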