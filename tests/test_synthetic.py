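"""Synthetic benchmark generator and session protocol."""

import numpy as np
import pytest

from fgde.frequency import frequency_components
from fgde.prototypes import PrototypeClassifier, extend_classifier, predict_batch
from fgde.synthetic import (SessionProtocol, SyntheticConfig, generate_dataset,
                            make_protocol, split_train_test)


class TestGenerateDataset:
    def test_balanced_counts(self):
        cfg = SyntheticConfig(n_classes=4, samples_per_class=10, seed=0)
        images, labels, manifest = generate_dataset(cfg)
        assert images.shape == (40, 32, 32, 3)
        assert np.bincount(labels).tolist() == [10] * 4
        assert manifest["n_classes"] == 4

    def test_values_in_unit_interval(self):
        cfg = SyntheticConfig(n_classes=3, samples_per_class=4, n_structure_groups=3, seed=1)
        images, _, _ = generate_dataset(cfg)
        assert images.min() >= 0.0 and images.max() <= 1.0

    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(n_classes=3, samples_per_class=5, n_structure_groups=2, seed=7)
        a, la, _ = generate_dataset(cfg)
        b, lb, _ = generate_dataset(cfg)
        assert np.array_equal(a, b) and np.array_equal(la, lb)

    def test_different_seeds_differ(self):
        a, _, _ = generate_dataset(SyntheticConfig(n_classes=2, samples_per_class=3,
                                                   n_structure_groups=1, seed=1))
        b, _, _ = generate_dataset(SyntheticConfig(n_classes=2, samples_per_class=3,
                                                   n_structure_groups=1, seed=2))
        assert not np.array_equal(a, b)

    def test_degenerate_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_classes=1)
        with pytest.raises(ValueError):
            SyntheticConfig(image_size=8)
        with pytest.raises(ValueError):
            SyntheticConfig(noise_sigma=-0.1)

    def test_structure_groups_share_low_frequency_layout(self):
        cfg = SyntheticConfig(n_classes=8, samples_per_class=6, n_structure_groups=4, seed=3)
        images, labels, manifest = generate_dataset(cfg)
        groups = {t["class"]: t["structure_group"] for t in manifest["texture_params"]}
        # mean low-frequency spectrum per class
        tau = 8
        means = {}
        for c in np.unique(labels):
            lows = [frequency_components(im, tau)[0] for im in images[labels == c][:4]]
            means[c] = np.mean(lows, axis=0)
        within, across = [], []
        classes = sorted(means)
        for i in classes:
            for j in classes:
                if i >= j:
                    continue
                d = np.linalg.norm(means[i] - means[j])
                (within if groups[i] == groups[j] else across).append(d)
        assert np.mean(within) < np.mean(across)

    def test_high_band_identifies_class_better_than_low_band(self):
        """Nearest-prototype on high-frequency spectral-magnitude features
        beats the same classifier on low-frequency features: class
        identity lives in the texture band by construction."""
        cfg = SyntheticConfig(n_classes=6, samples_per_class=12, seed=5)
        images, labels, _ = generate_dataset(cfg)
        tr, te = split_train_test(labels, seed=5)
        tau = 8

        def accuracy(band):
            def feats(im):
                lo, hi = frequency_components(im, tau)
                comp = lo if band == "low" else hi
                # spectral magnitude is phase-invariant
                from fgde.frequency import dct2
                return np.concatenate([np.abs(dct2(comp[:, :, c]).ravel()) for c in range(3)])

            clf = PrototypeClassifier(n_variants=1)
            sup = {}
            for c in np.unique(labels):
                idx = [i for i in tr if labels[i] == c]
                sup[c] = np.stack([feats(images[i]) for i in idx])
            extend_classifier(clf, sup, session=0)
            emb = np.stack([feats(images[i]) for i in te])[:, None, :]
            pred = predict_batch(emb, clf)
            return (pred == labels[te]).mean()

        assert accuracy("high") > accuracy("low")


class TestProtocol:
    def test_reference_protocol_uses_all_classes(self):
        p = make_protocol(28, 16, 4, 3, 5, seed=0)
        used = set(p.base_classes) | {c for s in p.sessions for c in s}
        assert used == set(range(28))
        assert all(len(s) == 3 for s in p.sessions)
        assert p.k_shot == 5

    def test_pure_base_protocol(self):
        p = make_protocol(8, 8, 0, 0, 1, seed=0)
        assert len(p.base_classes) == 8 and p.sessions == ()

    def test_disjointness_randomized(self):
        for seed in range(10):
            p = make_protocol(20, 10, 3, 3, 5, seed=seed)
            pools = [set(p.base_classes)] + [set(s) for s in p.sessions]
            for i in range(len(pools)):
                for j in range(i + 1, len(pools)):
                    assert pools[i].isdisjoint(pools[j])

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            make_protocol(10, 8, 2, 3, 5, seed=0)

    def test_encountered_accumulates(self):
        p = make_protocol(12, 8, 2, 2, 5, seed=1)
        assert len(p.encountered(0)) == 8
        assert len(p.encountered(1)) == 10
        assert len(p.encountered(2)) == 12

    def test_overlapping_sessions_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SessionProtocol(base_classes=(0, 1), sessions=((1, 2),), k_shot=5)


class TestSplit:
    def test_split_disjoint_and_covering(self):
        labels = np.repeat(np.arange(5), 8)
        tr, te = split_train_test(labels, train_frac=0.75, seed=0)
        assert set(tr).isdisjoint(te)
        assert len(tr) + len(te) == len(labels)
        for c in range(5):
            assert (labels[tr] == c).sum() == 6
            assert (labels[te] == c).sum() == 2
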