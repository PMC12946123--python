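"""Frequency-aware contrastive few-shot class-incremental classifier.

:class:`FGDEClassifier` is a scikit-learn-style estimator wrapping the
whole pipeline.  ``fit`` runs the base session: every image is expanded
into its transform variants (original, high/low-frequency fused, colour
jitter, rotation) with extended labels ``y*N + n``, and a query encoder is
trained with the unweighted sum of extended cross-entropy, the
momentum-queue contrastive loss and the prototype-softened augmentation
loss, while a key encoder tracks it by EMA and feeds the feature/label
queue.  ``extend`` runs an incremental session: the backbone stays frozen
and per-variant prototypes of the novel few-shot classes are appended to
the nearest-class-mean classifier.  ``predict`` embeds the variants of a
test image and sums cosine similarity against each class's variant
prototypes.
"""

from __future__ import annotations

import copy

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .augment import DEFAULT_TRANSFORMS, TransformSet, build_extended_batch, random_crop
from .contrastive import EncoderPair, PairQueue, batch_contrastive_loss, momentum_update
from .frequency import default_tau_cut
from .losses import (augmentation_grad, augmentation_loss, cross_entropy_grad,
                     extended_cross_entropy, total_loss)
from .nn import (SGD, Dense, Encoder, Sequential, build_backbone, l2_normalize,
                 l2_normalize_backward)
from .prototypes import PrototypeClassifier, extend_classifier, predict_batch
from scipy.special import softmax

__all__ = ["FGDEClassifier"]


class FGDEClassifier(BaseEstimator, ClassifierMixin):
    """Few-shot class-incremental classifier with frequency-aware
    domain extension and supervised contrastive base training.

    Parameters
    ----------
    backbone : {"small_cnn", "mlp"}
        Encoder architecture; ``small_cnn`` is the default two-block
        convolutional net, ``mlp`` a faster dense net for quick runs.
    embed_dim : int
        Dimension d of the representation h fed to the classifier head
        and (L2-normalised) to the contrastive loss and prototypes.
    transforms : sequence of str or None
        Label-extending variant transforms, applied in order; ``None``
        selects the default five-variant set.
    tau_cut : int or None
        Manhattan cut-off of the low-pass frequency mask; ``None`` uses
        ``floor((H + W) / 8)``.
    temperature : float
        Contrastive softmax temperature (as configured in the reference
        setting: 16).
    queue_momentum : float
        EMA coefficient m of the key encoder.
    queue_len : int
        Capacity of the feature/label queues.
    standard_denominator : bool
        If True the contrastive denominator includes positives
        (conventional supervised contrastive form); default keeps
        negatives only.
    epochs, batch_size, lr, sgd_momentum, lr_step, lr_gamma
        SGD training schedule for the base session.  ``batch_size``
        counts *images*; each step sees ``batch_size * N`` variants.
    crop : bool
        Apply a stochastic random crop (resized back) to every training
        image each epoch before variant expansion.
    augmentation_mode : {"soft", "hard"}
        ``soft`` softens augmentation-loss targets with prototype
        similarity; ``hard`` uses one-hot targets (plain cross-entropy).
    soft_target_temp : float
        Softmax temperature for prototype-derived soft targets.
    incremental_epochs : int
        Optional cosine-classifier refinement steps for novel prototypes
        during ``extend``; 0 (default) keeps the deterministic
        prototype-only path.
    random_state : int
        Seed for every source of randomness.
    """

    def __init__(
        self,
        backbone: str = "small_cnn",
        embed_dim: int = 64,
        transforms=None,
        tau_cut=None,
        temperature: float = 16.0,
        queue_momentum: float = 0.999,
        queue_len: int = 256,
        standard_denominator: bool = False,
        epochs: int = 100,
        batch_size: int = 16,
        lr: float = 0.1,
        sgd_momentum: float = 0.9,
        lr_step: int = 40,
        lr_gamma: float = 0.1,
        crop: bool = True,
        augmentation_mode: str = "soft",
        soft_target_temp: float = 0.1,
        incremental_epochs: int = 0,
        incremental_lr: float = 0.01,
        random_state: int = 0,
    ):
        self.backbone = backbone
        self.embed_dim = embed_dim
        self.transforms = transforms
        self.tau_cut = tau_cut
        self.temperature = temperature
        self.queue_momentum = queue_momentum
        self.queue_len = queue_len
        self.standard_denominator = standard_denominator
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.sgd_momentum = sgd_momentum
        self.lr_step = lr_step
        self.lr_gamma = lr_gamma
        self.crop = crop
        self.augmentation_mode = augmentation_mode
        self.soft_target_temp = soft_target_temp
        self.incremental_epochs = incremental_epochs
        self.incremental_lr = incremental_lr
        self.random_state = random_state

    # ------------------------------------------------------------------ utils

    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"X must be (n, H, W, 3), got shape {X.shape}")
        if X.shape[1] < 2 or X.shape[2] < 2:
            raise ValueError("images must be at least 2x2")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if X.min() < -1e-9 or X.max() > 1.0 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        return X

    def _rng(self, *tags: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.random_state) & 0x7FFFFFFF, *tags])
        )

    def _embed(self, images: np.ndarray, encoder: Encoder, chunk: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(images), chunk):
            out.append(encoder.features(images[i : i + chunk]))
        return np.concatenate(out) if out else np.empty((0, self.embed_dim))

    def _variant_embeddings(self, X: np.ndarray, seed_tag: int) -> np.ndarray:
        """(n, N, d) L2-normalised embeddings of every variant of X."""
        samples = build_extended_batch(
            X, np.zeros(len(X), dtype=int), self.transform_set_, self.tau_cut_,
            rng_seed=int(self._rng(seed_tag).integers(2**31)),
        )
        pixels = np.stack([s.pixels for s in samples])
        h = self._embed(pixels, self.encoder_)
        z = l2_normalize(h)
        return z.reshape(len(X), self.transform_set_.n_variants, self.embed_dim)

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        """Run the base session: contrastive training plus prototypes."""
        X = self._validate_images(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        base_classes, y_idx = np.unique(y, return_inverse=True)
        if len(base_classes) < 2:
            raise ValueError("need at least two base classes")

        names = list(self.transforms) if self.transforms is not None else list(DEFAULT_TRANSFORMS)
        self.transform_set_ = TransformSet(tuple(names))
        n_var = self.transform_set_.n_variants
        h_img, w_img = X.shape[1], X.shape[2]
        self.input_size_ = h_img
        self.tau_cut_ = int(self.tau_cut) if self.tau_cut is not None else default_tau_cut(h_img, w_img)

        rng = self._rng(11)
        net, layout = build_backbone(self.backbone, h_img, self.embed_dim, rng)
        n_ext = len(base_classes) * n_var
        head = Dense(self.embed_dim, n_ext, rng)
        self.encoder_ = Encoder(net, head, layout)
        self.key_encoder_ = copy.deepcopy(self.encoder_)
        pair = EncoderPair(self.encoder_, self.key_encoder_, momentum=self.queue_momentum)
        self.queue_ = PairQueue(self.queue_len, self.embed_dim)

        trainer = Sequential([*net.layers, head])
        opt = SGD(trainer, lr=self.lr, momentum=self.sgd_momentum,
                  lr_step=self.lr_step, lr_gamma=self.lr_gamma)

        # running per-extended-class prototypes for augmentation-loss targets
        ema_protos = np.zeros((n_ext, self.embed_dim))
        proto_seen = np.zeros(n_ext, dtype=bool)

        log_rows = []
        step = 0
        for epoch in range(self.epochs):
            opt.set_epoch(epoch)
            erng = self._rng(23, epoch)
            imgs = X
            if self.crop:
                lo_w = max(1, w_img // 2)
                lo_h = max(1, h_img // 2)
                imgs = np.stack([
                    random_crop(im, (lo_w, w_img), (lo_h, h_img), erng,
                                out_size=(h_img, w_img))
                    for im in X
                ])
            order = erng.permutation(len(imgs))
            for start in range(0, len(order), self.batch_size):
                sel = order[start : start + self.batch_size]
                samples = build_extended_batch(
                    imgs[sel], y_idx[sel], self.transform_set_, self.tau_cut_,
                    rng_seed=int(erng.integers(2**31)),
                )
                pixels = np.stack([s.pixels for s in samples])
                ext_labels = np.array([s.extended_label for s in samples])

                trainer.zero_grad()
                h = self.encoder_.features(pixels)
                z = l2_normalize(h)
                logits = self.encoder_.logits(h)

                ce = extended_cross_entropy(logits, ext_labels)
                d_logits = cross_entropy_grad(logits, ext_labels)

                # refresh EMA prototypes, then prototype-softened targets
                for cid in np.unique(ext_labels):
                    zc = z[ext_labels == cid].mean(axis=0)
                    if proto_seen[cid]:
                        ema_protos[cid] = 0.9 * ema_protos[cid] + 0.1 * zc
                    else:
                        ema_protos[cid] = zc
                        proto_seen[cid] = True
                weights = self._prototype_weights(ema_protos, proto_seen)
                al = augmentation_loss(softmax(logits, axis=1), weights, ext_labels)
                d_logits = d_logits + augmentation_grad(logits, weights, ext_labels)

                cl, dz = batch_contrastive_loss(
                    z, ext_labels, self.queue_, self.temperature,
                    standard_denominator=self.standard_denominator,
                )
                dh_cl = l2_normalize_backward(h, dz)

                bundle = total_loss(ce, cl, al)
                log_rows.append({"step": step, "epoch": epoch, **bundle.as_row()})
                step += 1

                dh = head.backward(d_logits) + dh_cl
                net.backward(dh)
                opt.step()

                momentum_update(pair)
                hk = self.key_encoder_.features(pixels)
                keep = min(len(hk), self.queue_.capacity)
                self.queue_.enqueue(l2_normalize(hk)[-keep:], ext_labels[-keep:])

        self.loss_log_ = pd.DataFrame(log_rows)
        self.classes_ = base_classes
        self.n_base_classes_ = len(base_classes)
        self.sessions_ = []

        # freeze-time prototypes over the untouched training images
        zvar = self._variant_embeddings(X, seed_tag=57)
        clf = PrototypeClassifier(n_variants=n_var)
        supports = {}
        for c in range(len(base_classes)):
            zc = zvar[y_idx == c]  # (n_c, N, d)
            for v in range(n_var):
                supports[c * n_var + v] = zc[:, v, :]
        extend_classifier(clf, supports, session=0)
        self.prototype_classifier_ = clf
        return self

    def _prototype_weights(self, protos: np.ndarray, seen: np.ndarray) -> np.ndarray:
        n_ext = len(protos)
        if self.augmentation_mode == "hard":
            return np.eye(n_ext)
        p = l2_normalize(np.where(seen[:, None], protos, 0.0))
        sims = p @ p.T / self.soft_target_temp
        sims[~seen] = -np.inf
        sims[:, ~seen] = -np.inf
        np.fill_diagonal(sims, np.where(seen, np.diag(sims), 0.0))
        w = np.zeros((n_ext, n_ext))
        for i in range(n_ext):
            if seen[i]:
                w[i] = softmax(np.where(np.isneginf(sims[i]), -1e30, sims[i]))
            else:
                w[i, i] = 1.0
        return w

    # ------------------------------------------------------------------ incremental

    def extend(self, X, y):
        """Incremental session: frozen backbone, new few-shot prototypes.

        ``y`` must contain only classes never seen before.  Existing
        prototypes and all encoder parameters are untouched.
        """
        check_is_fitted(self, "prototype_classifier_")
        X = self._validate_images(X)
        y = np.asarray(y)
        novel = np.unique(y)
        overlap = set(novel.tolist()) & set(self.classes_.tolist())
        if overlap:
            raise ValueError(f"classes already known: {sorted(overlap)}")
        session = len(self.sessions_) + 1
        n_var = self.transform_set_.n_variants
        offset = len(self.classes_)

        zvar = self._variant_embeddings(X, seed_tag=57 + session)
        supports = {}
        for j, c in enumerate(novel):
            zc = zvar[y == c]
            internal = offset + j
            for v in range(n_var):
                supports[internal * n_var + v] = zc[:, v, :]
        extend_classifier(self.prototype_classifier_, supports, session=session)
        if self.incremental_epochs > 0:
            self._refine_novel_prototypes(supports, session)
        self.classes_ = np.concatenate([self.classes_, novel])
        self.sessions_.append({"session": session, "classes": novel.tolist(),
                               "k_shot": int(np.bincount(np.searchsorted(novel, y)).min())})
        return self

    def _refine_novel_prototypes(self, supports: dict[int, np.ndarray], session: int):
        """Cosine-classifier refinement of the *novel* prototypes only.

        Novel support embeddings are contrasted against the frozen base
        feature queue: each refinement epoch nudges a novel prototype
        toward its supports and away from queue entries it confuses with,
        via gradient steps on a cosine-softmax cross-entropy.  Base
        prototypes and the backbone are never touched.
        """
        clf = self.prototype_classifier_
        queue_feats = self.queue_.features
        for _ in range(self.incremental_epochs):
            for cid, emb in supports.items():
                proto = clf.prototypes[cid]
                w = proto.vector.copy()
                wn = w / max(np.linalg.norm(w), 1e-12)
                pull = l2_normalize(emb).mean(axis=0)
                if len(queue_feats):
                    sims = queue_feats @ wn
                    push = (softmax(sims / 0.5) [:, None] * queue_feats).sum(axis=0)
                else:
                    push = 0.0
                w = w + self.incremental_lr * (pull - 0.5 * push)
                clf.prototypes[cid] = type(proto)(
                    vector=w, class_id=proto.class_id,
                    session_index=proto.session_index,
                    support_count=proto.support_count,
                )

    # ------------------------------------------------------------------ predict

    def predict(self, X):
        check_is_fitted(self, "prototype_classifier_")
        X = self._validate_images(X)
        zvar = self._variant_embeddings(X, seed_tag=911)
        internal = predict_batch(zvar, self.prototype_classifier_)
        return self.classes_[internal]

    def decision_scores(self, X) -> np.ndarray:
        """Summed per-class cosine scores, one row per image."""
        check_is_fitted(self, "prototype_classifier_")
        X = self._validate_images(X)
        zvar = self._variant_embeddings(X, seed_tag=911)
        clf = self.prototype_classifier_
        n = clf.n_variants
        base = clf.base_classes
        protos = np.stack([
            np.stack([clf.prototypes[y * n + v].vector for v in range(n)]) for y in base
        ])
        pn = protos / np.linalg.norm(protos, axis=2, keepdims=True)
        return np.einsum("ivd,cvd->ic", zvar, pn)
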