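"""Training objectives: extended cross-entropy, prototype-guided feature
augmentation loss, and their unweighted sum.

The total objective is ``L = L_ce + L_cl + L_al`` with no weighting
coefficients: cross-entropy over the extended label space, the contrastive
loss from :mod:`fgde.contrastive`, and a global feature-augmentation loss
whose targets are softened by class-prototype similarity (collapsing to
plain cross-entropy when the prototype weight rows are one-hot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

__all__ = [
    "LossBundle",
    "extended_cross_entropy",
    "cross_entropy_grad",
    "augmentation_loss",
    "augmentation_grad",
    "total_loss",
]


@dataclass(frozen=True)
class LossBundle:
    """Per-step loss components; ``total`` is their exact fp sum."""

    ce: float
    contrastive: float
    augmentation: float
    total: float

    def as_row(self) -> dict[str, float]:
        return {"ce": self.ce, "cl": self.contrastive, "al": self.augmentation,
                "total": self.total}


def _check_logits_labels(logits, labels):
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if logits.ndim != 2:
        raise ValueError("logits must be 2-D (batch x classes)")
    if labels.ndim != 1 or len(labels) != len(logits):
        raise ValueError("labels must be 1-D and match the batch size")
    if labels.min(initial=0) < 0 or (len(labels) and labels.max() >= logits.shape[1]):
        raise ValueError("label out of range for logit width")
    return logits, labels


def extended_cross_entropy(logits: np.ndarray, extended_labels: np.ndarray) -> float:
    """Mean negative log-softmax at the extended-label targets."""
    logits, labels = _check_logits_labels(logits, extended_labels)
    logp = log_softmax(logits, axis=1)
    return float(-logp[np.arange(len(labels)), labels].mean())


def cross_entropy_grad(logits: np.ndarray, extended_labels: np.ndarray) -> np.ndarray:
    """Gradient of :func:`extended_cross_entropy` w.r.t. the logits."""
    logits, labels = _check_logits_labels(logits, extended_labels)
    p = softmax(logits, axis=1)
    p[np.arange(len(labels)), labels] -= 1.0
    return p / len(labels)


def _check_probs(probabilities):
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("probabilities must be 2-D")
    if np.any(p < -1e-12) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must be nonnegative and sum to 1")
    return np.clip(p, 1e-300, None)


def augmentation_loss(
    probabilities: np.ndarray,
    prototype_weights: np.ndarray,
    assignments: np.ndarray,
) -> float:
    """Soft-target cross-entropy against prototype-derived targets.

    ``prototype_weights[c]`` is the target distribution for class ``c``
    (rows sum to 1); sample ``i`` with assignment ``c_i`` contributes
    ``-sum_k W[c_i, k] log p_i[k]``, averaged over the batch.  One-hot
    weight rows reduce this exactly to hard cross-entropy.
    """
    p = _check_probs(probabilities)
    w = np.asarray(prototype_weights, dtype=np.float64)
    assignments = np.asarray(assignments, dtype=np.int64)
    if w.ndim != 2 or w.shape[1] != p.shape[1]:
        raise ValueError("prototype weight width must match probability width")
    if len(assignments) != len(p):
        raise ValueError("assignments must match the batch size")
    if assignments.min(initial=0) < 0 or (len(assignments) and assignments.max() >= len(w)):
        raise ValueError("assignment out of range for prototype weights")
    targets = w[assignments]
    return float(-(targets * np.log(p)).sum(axis=1).mean())


def augmentation_grad(
    logits: np.ndarray,
    prototype_weights: np.ndarray,
    assignments: np.ndarray,
) -> np.ndarray:
    """Gradient of the augmentation loss w.r.t. logits feeding a softmax."""
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(prototype_weights, dtype=np.float64)[np.asarray(assignments, dtype=np.int64)]
    return (softmax(logits, axis=1) - targets) / len(logits)


def total_loss(ce: float, contrastive: float, augmentation: float) -> LossBundle:
    """Unweighted sum of the three components.

    A non-finite component signals a diverged training step; the caller
    aborts on the raised error rather than continuing with a poisoned
    model.
    """
    parts = {"ce": ce, "contrastive": contrastive, "augmentation": augmentation}
    for name, value in parts.items():
        if not np.isfinite(value):
            raise FloatingPointError(f"non-finite {name} loss component: {value}")
    return LossBundle(ce=float(ce), contrastive=float(contrastive),
                      augmentation=float(augmentation),
                      total=float(ce) + float(contrastive) + float(augmentation))
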