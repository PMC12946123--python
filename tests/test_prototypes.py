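"""Prototype classifier: means, distances, extension, cosine inference."""

import numpy as np
import pytest

from fgde.nn import l2_normalize
from fgde.prototypes import (PrototypeClassifier, compute_prototype,
                             extend_classifier, inter_class_distance,
                             intra_class_distance, predict, predict_batch)


class TestComputePrototype:
    def test_single_vector_is_its_own_prototype(self):
        p = compute_prototype(np.array([[1.0, 2.0, 3.0]]))
        assert np.array_equal(p.vector, [1.0, 2.0, 3.0])
        assert p.support_count == 1

    def test_midpoint(self):
        p = compute_prototype(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert np.array_equal(p.vector, [1.0, 1.0])

    def test_matches_explicit_summation(self, rng):
        emb = rng.normal(size=(50, 8))
        ref = np.zeros(8)
        for v in emb:
            ref += v
        ref /= 50
        assert np.allclose(compute_prototype(emb).vector, ref, atol=1e-12)

    def test_empty_support_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_prototype(np.empty((0, 4)))


class TestDistances:
    def test_identical_prototypes_distance_zero(self):
        p = compute_prototype(np.array([[1.0, 2.0]]))
        assert inter_class_distance(p, p) == 0.0

    def test_three_four_five(self):
        p = compute_prototype(np.array([[0.0, 0.0]]))
        q = compute_prototype(np.array([[3.0, 4.0]]))
        assert inter_class_distance(p, q) == 5.0

    def test_symmetry(self, rng):
        for _ in range(10):
            p = compute_prototype(rng.normal(size=(1, 6)))
            q = compute_prototype(rng.normal(size=(1, 6)))
            assert inter_class_distance(p, q) == inter_class_distance(q, p)

    def test_intra_all_at_prototype_is_zero(self):
        p = compute_prototype(np.array([[1.0, 1.0]]))
        assert intra_class_distance(np.ones((5, 2)), p) == 0.0

    def test_intra_symmetric_pair_is_radius(self):
        p = compute_prototype(np.array([[0.0, 0.0]]))
        members = np.array([[3.0, 0.0], [-3.0, 0.0]])
        assert intra_class_distance(members, p) == pytest.approx(3.0)

    def test_intra_matches_loop(self, rng):
        emb = rng.normal(size=(20, 5))
        p = compute_prototype(emb)
        ref = np.mean([np.linalg.norm(e - p.vector) for e in emb])
        assert intra_class_distance(emb, p) == pytest.approx(ref, abs=1e-12)


class TestExtendClassifier:
    def _base_classifier(self, rng, n_classes=16, n_var=5, d=8):
        clf = PrototypeClassifier(n_variants=n_var)
        supports = {c * n_var + v: rng.normal(size=(3, d))
                    for c in range(n_classes) for v in range(n_var)}
        extend_classifier(clf, supports, session=0)
        return clf

    def test_session_adds_exactly_novel_times_n_prototypes(self, rng):
        clf = self._base_classifier(rng)
        assert len(clf.prototypes) == 16 * 5
        novel = {c * 5 + v: rng.normal(size=(2, 8))
                 for c in range(16, 19) for v in range(5)}
        extend_classifier(clf, novel, session=1)
        assert len(clf.prototypes) == 19 * 5 == 95

    def test_empty_session_changes_nothing(self, rng):
        clf = self._base_classifier(rng, n_classes=2)
        before = {k: v.vector.copy() for k, v in clf.prototypes.items()}
        extend_classifier(clf, {}, session=1)
        assert set(clf.prototypes) == set(before)

    def test_prior_prototypes_bit_identical_after_extension(self, rng):
        clf = self._base_classifier(rng, n_classes=3)
        before = {k: v.vector.copy() for k, v in clf.prototypes.items()}
        novel = {3 * 5 + v: rng.normal(size=(2, 8)) for v in range(5)}
        extend_classifier(clf, novel, session=1)
        for k, vec in before.items():
            assert np.array_equal(clf.prototypes[k].vector, vec)

    def test_label_collision_rejected(self, rng):
        clf = self._base_classifier(rng, n_classes=2)
        with pytest.raises(ValueError, match="already present"):
            extend_classifier(clf, {0: rng.normal(size=(1, 8))}, session=1)


class TestPredict:
    def _clf_from_protos(self, protos):
        """protos: (n_classes, n_var, d)"""
        n_cls, n_var, _ = protos.shape
        clf = PrototypeClassifier(n_variants=n_var)
        supports = {c * n_var + v: protos[c, v][None] for c in range(n_cls) for v in range(n_var)}
        extend_classifier(clf, supports, session=0)
        return clf

    def test_exact_prototype_match_wins(self, rng):
        protos = rng.normal(size=(4, 3, 6))
        clf = self._clf_from_protos(protos)
        assert predict(protos[2], clf) == 2

    def test_tie_breaks_to_lowest_class(self):
        protos = np.array([[[1.0, 0.0]], [[1.0, 0.0]]])  # two identical classes
        clf = self._clf_from_protos(protos)
        assert predict(np.array([[1.0, 0.0]]), clf) == 0
        assert predict_batch(np.array([[[1.0, 0.0]]]), clf)[0] == 0

    def test_matches_exhaustive_double_loop(self, rng):
        for _ in range(25):
            protos = rng.normal(size=(6, 2, 8))
            clf = self._clf_from_protos(protos)
            emb = rng.normal(size=(2, 8))
            best, best_s = -1, -np.inf
            for y in range(6):
                s = sum(
                    float(emb[v] @ protos[y, v]
                          / (np.linalg.norm(emb[v]) * np.linalg.norm(protos[y, v])))
                    for v in range(2)
                )
                if s > best_s:
                    best, best_s = y, s
            assert predict(emb, clf) == best
            assert predict_batch(emb[None], clf)[0] == best

    def test_invariant_to_common_positive_rescaling(self, rng):
        protos = rng.normal(size=(5, 3, 4))
        clf = self._clf_from_protos(protos)
        emb = rng.normal(size=(3, 4))
        assert predict(emb, clf) == predict(7.3 * emb, clf)

    def test_zero_norm_embedding_rejected(self, rng):
        protos = rng.normal(size=(2, 1, 4))
        clf = self._clf_from_protos(protos)
        with pytest.raises(ValueError, match="zero-norm"):
            predict(np.zeros((1, 4)), clf)

    def test_variant_count_mismatch_rejected(self, rng):
        protos = rng.normal(size=(2, 3, 4))
        clf = self._clf_from_protos(protos)
        with pytest.raises(ValueError, match="variant"):
            predict(rng.normal(size=(2, 4)), clf)
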