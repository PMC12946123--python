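"""Evaluation surface: confusion-matrix metrics, session accuracies,
harmonic mean of base/incremental accuracy, and improvement deltas.

All rates are reported as percentages in [0, 100].  One-vs-rest metrics
with a zero denominator are reported as 0 together with a ``degenerate``
flag rather than NaN, so near-empty rows of a class report stay usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "SessionReport",
    "confusion_from_predictions",
    "basic_metrics",
    "f1_from_pr",
    "harmonic_mean",
    "improvement",
    "micro_accuracy",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer count matrix, rows = true class, columns = predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.int64)
            if np.any(counts < 0):
                raise ValueError("confusion matrix counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        if not self.class_names:
            object.__setattr__(
                self, "class_names", tuple(str(i) for i in range(counts.shape[0]))
            )

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_predictions(y_true, y_pred, labels=None) -> ConfusionMatrix:
    counts = _sk_confusion_matrix(y_true, y_pred, labels=labels)
    names = tuple(str(c) for c in (labels if labels is not None else sorted(set(y_true) | set(y_pred))))
    return ConfusionMatrix(counts=counts, class_names=names)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest rates for a single class, in percent."""

    precision: float
    recall: float
    specificity: float
    f1: float
    degenerate: bool = False


def _safe_pct(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return 100.0 * num / den, False


def basic_metrics(cm: ConfusionMatrix, class_index: int) -> ClassMetrics:
    """Precision, recall, specificity and F1 for one class (percent).

    Counts are one-vs-rest: TP the diagonal cell, FP the rest of the
    column, FN the rest of the row, TN everything else.
    """
    c = cm.counts
    if not (0 <= class_index < cm.n_classes):
        raise ValueError("class index out of range")
    tp = int(c[class_index, class_index])
    fp = int(c[:, class_index].sum()) - tp
    fn = int(c[class_index, :].sum()) - tp
    tn = cm.total - tp - fp - fn
    precision, d1 = _safe_pct(tp, tp + fp)
    recall, d2 = _safe_pct(tp, tp + fn)
    specificity, d3 = _safe_pct(tn, fp + tn)
    if precision + recall == 0:
        f1, d4 = 0.0, True
    else:
        f1, d4 = f1_from_pr(precision, recall), False
    return ClassMetrics(precision=precision, recall=recall, specificity=specificity,
                        f1=f1, degenerate=d1 or d2 or d3 or d4)


def f1_from_pr(precision: float, recall: float) -> float:
    """F1 = 2 P R / (P + R), with inputs and output in percent."""
    if not (0 <= precision <= 100 and 0 <= recall <= 100):
        raise ValueError("precision/recall must be percentages in [0, 100]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def harmonic_mean(a_base: float, a_inc: float) -> float:
    """HM = 2ab/(a+b) of base and incremental accuracy (percent).

    Balances the bias toward the data-rich base classes against few-shot
    incremental classes; always <= the arithmetic mean.
    """
    if not (0 < a_base <= 100 and 0 < a_inc <= 100):
        raise ValueError("accuracies must lie in (0, 100]")
    return 2.0 * a_base * a_inc / (a_base + a_inc)


def improvement(hm_method: float, hm_reference: float) -> float:
    """Delta of harmonic means, method minus reference (percentage points)."""
    return hm_method - hm_reference


def micro_accuracy(cm: ConfusionMatrix) -> float:
    """Overall top-1 accuracy in percent: trace / total."""
    if cm.total == 0:
        return 0.0
    return 100.0 * float(np.trace(cm.counts)) / cm.total


@dataclass
class SessionReport:
    """Session-wise accuracies of one incremental run, in percent."""

    base_accuracy: float
    session_accuracies: list[float] = field(default_factory=list)
    a_base_final: float = 0.0
    a_inc_pooled: float = 0.0
    hm: float = 0.0
    improvement_vs_reference: float | None = None

    def as_dict(self) -> dict:
        return {
            "base_accuracy": self.base_accuracy,
            "session_accuracies": list(self.session_accuracies),
            "a_base_final": self.a_base_final,
            "a_inc_pooled": self.a_inc_pooled,
            "hm": self.hm,
            "improvement_vs_reference": self.improvement_vs_reference,
        }
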