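"""Supervised contrastive machinery: momentum encoder pair, feature/label
queues, positive/negative set construction and the InfoNCE objective.

The query encoder is trained by gradient descent; the key encoder tracks
it by exponential moving average and feeds a FIFO queue of key embeddings
with a parallel queue of extended labels.  An anchor's positives are the
label-matched candidates (batch and queue alike), its negatives all
label-mismatched candidates.

The loss as configured by default normalises the softmax over negatives
only, so a well-separated anchor can attain a negative loss; the
``standard_denominator`` switch restores the conventional supervised
contrastive form whose denominator includes the positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import Encoder

logger = logging.getLogger(__name__)

__all__ = [
    "EncoderPair",
    "PairQueue",
    "momentum_update",
    "build_pos_neg_sets",
    "info_nce_loss",
    "batch_contrastive_loss",
]


@dataclass
class EncoderPair:
    """Query encoder (gradient-trained) and its momentum key copy."""

    query: Encoder
    key: Encoder
    momentum: float = 0.999

    def __post_init__(self):
        if not (0.0 <= self.momentum <= 1.0):
            raise ValueError("momentum must lie in [0, 1]")
        q_shapes = [layer.params[name].shape for layer, name in self.query.all_params()]
        k_shapes = [layer.params[name].shape for layer, name in self.key.all_params()]
        if q_shapes != k_shapes:
            raise ValueError("query and key encoder architectures do not match")


def momentum_update(pair: EncoderPair) -> EncoderPair:
    """EMA update of every key parameter: ``p_k <- m p_k + (1 - m) p_q``.

    With momentum < 1 repeated updates under a frozen query contract the
    key encoder onto the query encoder.
    """
    m = pair.momentum
    q_params = list(pair.query.all_params())
    k_params = list(pair.key.all_params())
    if len(q_params) != len(k_params):
        raise ValueError("query and key encoder architectures do not match")
    for (ql, qn), (kl, kn) in zip(q_params, k_params):
        if ql.params[qn].shape != kl.params[kn].shape:
            raise ValueError("query and key encoder architectures do not match")
        kl.params[kn][...] = m * kl.params[kn] + (1.0 - m) * ql.params[qn]
    return pair


class PairQueue:
    """Fixed-capacity FIFO holding key embeddings and their labels.

    The two buffers always have equal length; entries are stored oldest
    first and evicted together, so feature/label provenance stays aligned.
    """

    def __init__(self, capacity: int, dim: int):
        if capacity < 1:
            raise ValueError("queue capacity must be >= 1")
        self.capacity = int(capacity)
        self.dim = int(dim)
        self.features = np.empty((0, self.dim))
        self.labels = np.empty((0,), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.labels)

    def enqueue(self, embeddings: np.ndarray, labels: np.ndarray) -> "PairQueue":
        embeddings = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
        labels = np.atleast_1d(np.asarray(labels, dtype=np.int64))
        if embeddings.shape[1] != self.dim:
            raise ValueError(f"embedding dim {embeddings.shape[1]} != queue dim {self.dim}")
        if len(embeddings) != len(labels):
            raise ValueError("embeddings/labels length mismatch")
        if len(embeddings) > self.capacity:
            raise ValueError("batch larger than queue capacity")
        self.features = np.concatenate([self.features, embeddings])[-self.capacity:]
        self.labels = np.concatenate([self.labels, labels])[-self.capacity:]
        return self


def build_pos_neg_sets(anchor_index: int, labels: np.ndarray | list[int]) -> tuple[set[int], set[int]]:
    """Split candidate indices into positives Q_i and negatives K_i.

    Positives share the anchor's label (anchor itself excluded); negatives
    are every differently-labelled index.  The two sets partition the
    candidate pool minus the anchor.
    """
    labels = np.asarray(labels)
    if not (0 <= anchor_index < len(labels)):
        raise ValueError(f"anchor index {anchor_index} out of range")
    anchor_label = labels[anchor_index]
    same = labels == anchor_label
    positives = set(np.flatnonzero(same).tolist()) - {anchor_index}
    negatives = set(np.flatnonzero(~same).tolist())
    return positives, negatives


def info_nce_loss(
    anchor_emb: np.ndarray,
    candidate_embs: np.ndarray,
    positives: set[int],
    negatives: set[int],
    temperature: float,
    standard_denominator: bool = False,
) -> float:
    """Temperature-scaled contrastive loss for one anchor.

    ``-(1/|Q|) sum_{j in Q} log[ exp(s_ij / t) / D ]`` with similarities
    ``s`` the dot products of (already normalised) embeddings.  By default
    the denominator ``D`` sums over negatives only; with
    ``standard_denominator`` it sums over negatives and positives.

    An anchor with no positives has no defined loss and must be skipped by
    the caller; with no negatives the contribution is 0 (logged).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if len(positives) == 0:
        raise ValueError("anchor has no positives; skip it instead of calling")
    if len(negatives) == 0 and not standard_denominator:
        logger.warning("anchor has no negatives; contrastive contribution set to 0")
        return 0.0
    anchor_emb = np.asarray(anchor_emb, dtype=np.float64)
    candidate_embs = np.asarray(candidate_embs, dtype=np.float64)
    sims = candidate_embs @ anchor_emb / temperature
    pos_idx = np.fromiter(positives, dtype=np.int64)
    neg_idx = np.fromiter(negatives, dtype=np.int64) if negatives else np.empty(0, dtype=np.int64)
    denom_idx = np.concatenate([neg_idx, pos_idx]) if standard_denominator else neg_idx
    from scipy.special import logsumexp

    log_denom = logsumexp(sims[denom_idx])
    return float(-(sims[pos_idx] - log_denom).mean())


def batch_contrastive_loss(
    embeddings: np.ndarray,
    labels: np.ndarray,
    queue: PairQueue | None,
    temperature: float,
    standard_denominator: bool = False,
) -> tuple[float, np.ndarray]:
    """Mean anchor loss over a batch plus its gradient w.r.t. the batch
    embeddings.

    Candidates for each anchor are the other batch embeddings plus the
    queue contents.  Candidates are treated as constants (the usual
    momentum-queue convention): gradients flow only through each anchor's
    own embedding.  Anchors without positives are skipped; if every anchor
    is skipped the loss is 0 with a zero gradient.
    """
    embeddings = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n = len(embeddings)
    if queue is not None and len(queue):
        cand = np.concatenate([embeddings, queue.features])
        cand_labels = np.concatenate([labels, queue.labels])
    else:
        cand = embeddings
        cand_labels = labels

    grad = np.zeros_like(embeddings)
    losses = []
    t = temperature
    for i in range(n):
        pos_mask = cand_labels == labels[i]
        pos_mask[i] = False
        neg_mask = cand_labels != labels[i]
        n_pos = int(pos_mask.sum())
        if n_pos == 0:
            continue
        if not neg_mask.any() and not standard_denominator:
            logger.warning("anchor %d has no negatives; contribution 0", i)
            losses.append(0.0)
            continue
        sims = cand @ embeddings[i] / t
        denom_mask = (neg_mask | pos_mask) if standard_denominator else neg_mask
        m = sims[denom_mask].max()
        exp_shift = np.exp(sims[denom_mask] - m)
        log_denom = m + np.log(exp_shift.sum())
        losses.append(float(log_denom - sims[pos_mask].mean()))
        # dL/ds = softmax over denominator minus uniform mass on positives
        ds = np.zeros(len(cand))
        ds[denom_mask] = exp_shift / exp_shift.sum()
        ds[pos_mask] -= 1.0 / n_pos
        grad[i] += (cand.T @ ds) / t
    if not losses:
        return 0.0, grad
    grad /= len(losses)
    return float(np.mean(losses)), grad
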