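"""Nearest-class-mean prototype classifier grown across incremental
sessions.

Each extended class (base class x transform variant) owns one prototype:
the arithmetic mean of its support embeddings.  Incremental sessions add
prototypes for novel classes while the backbone and every previously
stored prototype stay frozen — the stability half of the
stability/plasticity trade-off.  Inference scores a test image by summing,
over its transform variants, the cosine similarity between the variant's
embedding and the matching variant prototype of each base class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Prototype",
    "PrototypeClassifier",
    "compute_prototype",
    "inter_class_distance",
    "intra_class_distance",
    "extend_classifier",
    "predict",
]


@dataclass(frozen=True)
class Prototype:
    """Mean support embedding for one extended class."""

    vector: np.ndarray
    class_id: int
    session_index: int
    support_count: int

    def __post_init__(self):
        object.__setattr__(self, "vector", np.asarray(self.vector, dtype=np.float64))
        if self.support_count < 1:
            raise ValueError("prototype needs at least one support embedding")


@dataclass
class PrototypeClassifier:
    """Map extended class id -> prototype; prototypes are append-only."""

    n_variants: int
    prototypes: dict[int, Prototype] = field(default_factory=dict)
    sessions_seen: int = 0

    @property
    def base_classes(self) -> list[int]:
        return sorted({cid // self.n_variants for cid in self.prototypes})

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked prototype vectors and their extended class ids."""
        ids = np.array(sorted(self.prototypes), dtype=np.int64)
        vecs = np.stack([self.prototypes[i].vector for i in ids]) if len(ids) else np.empty((0, 0))
        return vecs, ids


def compute_prototype(
    embeddings: np.ndarray, class_id: int = 0, session_index: int = 0
) -> Prototype:
    """Arithmetic mean of the support embeddings of one class."""
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if embeddings.size == 0:
        raise ValueError("cannot build a prototype from an empty support set")
    return Prototype(
        vector=embeddings.mean(axis=0),
        class_id=int(class_id),
        session_index=int(session_index),
        support_count=len(embeddings),
    )


def inter_class_distance(p_j: Prototype, p_k: Prototype) -> float:
    """Euclidean distance between two class prototypes."""
    if p_j.vector.shape != p_k.vector.shape:
        raise ValueError("prototype dimensions differ")
    return float(np.linalg.norm(p_j.vector - p_k.vector))


def intra_class_distance(embeddings: np.ndarray, prototype: Prototype) -> float:
    """Mean Euclidean distance of class members to their prototype."""
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    if embeddings.size == 0:
        raise ValueError("intra-class distance needs at least one member")
    return float(np.linalg.norm(embeddings - prototype.vector, axis=1).mean())


def extend_classifier(
    classifier: PrototypeClassifier,
    support_embeddings: dict[int, np.ndarray],
    session: int,
) -> PrototypeClassifier:
    """Append prototypes for novel extended classes; never mutate old ones.

    ``support_embeddings`` maps extended class id -> support embedding
    stack.  A collision with an existing class id is rejected: prototypes
    from closed sessions are immutable.
    """
    collisions = set(support_embeddings) & set(classifier.prototypes)
    if collisions:
        raise ValueError(f"extended classes already present: {sorted(collisions)}")
    for cid, emb in support_embeddings.items():
        classifier.prototypes[int(cid)] = compute_prototype(emb, class_id=int(cid),
                                                            session_index=session)
    if support_embeddings:
        classifier.sessions_seen = max(classifier.sessions_seen, session + 1)
    return classifier


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-norm embedding in cosine similarity")
    return float(a @ b / (na * nb))


def predict(variant_embeddings: np.ndarray, classifier: PrototypeClassifier) -> int:
    """Classify one test image from its N variant embeddings.

    Scores base class ``y`` as ``sum_n cos(e_n, prototype[y*N + n])`` and
    returns the argmax; ties break to the lowest class id.
    """
    if not classifier.prototypes:
        raise ValueError("classifier has no prototypes")
    variant_embeddings = np.atleast_2d(np.asarray(variant_embeddings, dtype=np.float64))
    n = classifier.n_variants
    if len(variant_embeddings) != n:
        raise ValueError(
            f"expected {n} variant embeddings, got {len(variant_embeddings)}"
        )
    best_class = -1
    best_score = -np.inf
    for y in classifier.base_classes:
        score = 0.0
        for v in range(n):
            proto = classifier.prototypes.get(y * n + v)
            if proto is None:
                raise ValueError(f"missing prototype for class {y} variant {v}")
            score += _cosine(variant_embeddings[v], proto.vector)
        if score > best_score:  # strict: ties keep the lowest class id
            best_score = score
            best_class = y
    return best_class


def predict_batch(all_variant_embeddings: np.ndarray, classifier: PrototypeClassifier) -> np.ndarray:
    """Vectorised :func:`predict` for a (n_images, N, d) embedding stack."""
    x = np.asarray(all_variant_embeddings, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected (n_images, n_variants, dim)")
    n_img, n, d = x.shape
    if n != classifier.n_variants:
        raise ValueError("variant count mismatch")
    norms = np.linalg.norm(x, axis=2)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm embedding in cosine similarity")
    xn = x / norms[:, :, None]
    base = classifier.base_classes
    protos = np.stack([
        np.stack([classifier.prototypes[y * n + v].vector for v in range(n)])
        for y in base
    ])  # (n_classes, N, d)
    pn = protos / np.linalg.norm(protos, axis=2, keepdims=True)
    scores = np.einsum("ivd,cvd->ic", xn, pn)  # summed cosine over variants
    return np.array(base, dtype=np.int64)[scores.argmax(axis=1)]
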