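"""Synthetic fine-grained image benchmark with controllable frequency
structure.

Real fine-grained plant data has low inter-class variance (species differ
in subtle texture detail) and high intra-class variance (pose, layout and
illumination vary freely within a species).  The generator reproduces that
signature directly in the frequency domain:

* classes are partitioned into *structure groups* that share a smooth
  low-frequency colour layout (a random blob field), so global appearance
  does **not** identify the class;
* each class adds a high-frequency sinusoidal grating whose spatial
  frequency and colour mix are the class signature, so identity is
  carried by the high band and survives pose changes;
* per-sample jitter (grating orientation, layout shift, rotation,
  brightness, texture phase) plus Gaussian pixel noise provides
  intra-class variation — pose varies freely within a class.

Class sizes are balanced, splits are disjoint by sample id, and every
array is bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _resize

__all__ = [
    "SyntheticConfig",
    "SessionProtocol",
    "generate_dataset",
    "make_protocol",
    "split_train_test",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults follow the desk-scale test profile."""

    n_classes: int = 12
    image_size: int = 32
    samples_per_class: int = 40
    n_structure_groups: int = 4
    texture_freq_band: tuple[float, float] = (5.0, 10.0)  # cycles per image width
    texture_amplitude: float = 0.14
    layout_shift_frac: float = 0.15
    rotation_jitter_deg: float = 8.0
    brightness_jitter: float = 0.1
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.samples_per_class < 2:
            raise ValueError("samples_per_class must be >= 2")
        if self.n_structure_groups < 1 or self.n_structure_groups > self.n_classes:
            raise ValueError("n_structure_groups must lie in [1, n_classes]")
        if not (0 < self.texture_freq_band[0] < self.texture_freq_band[1]):
            raise ValueError("texture_freq_band must be an increasing positive pair")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def _group_layout(rng: np.random.Generator, size: int) -> np.ndarray:
    """Smooth low-frequency colour field shared by one structure group."""
    coarse = rng.uniform(0.25, 0.75, size=(4, 4, 3))
    layout = _resize(coarse, (size, size, 3), order=3, mode="edge", anti_aliasing=False)
    return np.clip(layout, 0.0, 1.0)


#: well-spread unit colour directions for texture signatures
_COLOR_MIXES = np.array([
    [1.0, 0.15, 0.15],
    [0.15, 1.0, 0.15],
    [0.15, 0.15, 1.0],
    [0.7, 0.7, 0.1],
])
_COLOR_MIXES /= np.linalg.norm(_COLOR_MIXES, axis=1, keepdims=True)


def _class_texture_params(rng: np.random.Generator, n_classes: int,
                          band: tuple[float, float]) -> list[tuple[float, np.ndarray]]:
    """Pose-invariant texture signature per class.

    Identity is carried by the grating's spatial frequency and its colour
    mix — both unchanged by rotation and layout shift, so pose can vary
    freely within a class.  Frequencies and colour mixes are paired so no
    two classes share both.
    """
    n_freqs = int(np.ceil(n_classes / len(_COLOR_MIXES)))
    freqs = np.linspace(band[0], band[1], n_freqs)
    combos = [(float(freqs[i % n_freqs]), _COLOR_MIXES[(i // n_freqs) % len(_COLOR_MIXES)])
              for i in range(n_classes)]
    order = rng.permutation(n_classes)
    return [combos[order[i]] for i in range(n_classes)]


def _grating(size: int, freq: float, angle: float, phase: float) -> np.ndarray:
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    coord = xx * np.cos(angle) + yy * np.sin(angle)
    return np.sin(2.0 * np.pi * freq * coord / size + phase)


def generate_dataset(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate balanced labelled images plus a manifest.

    Returns ``(images, labels, manifest)`` with images shaped
    ``(n_classes * samples_per_class, S, S, 3)`` in [0, 1].
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7901]))
    s = config.image_size
    layouts = [_group_layout(rng, s) for _ in range(config.n_structure_groups)]
    textures = _class_texture_params(rng, config.n_classes, config.texture_freq_band)

    images = np.empty((config.n_classes * config.samples_per_class, s, s, 3))
    labels = np.empty(len(images), dtype=np.int64)
    max_shift = max(1, int(round(config.layout_shift_frac * s)))
    idx = 0
    for c in range(config.n_classes):
        group = c % config.n_structure_groups
        freq, color_mix = textures[c]
        for _ in range(config.samples_per_class):
            layout = layouts[group]
            dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
            img = np.roll(layout, (int(dy), int(dx)), axis=(0, 1)).copy()
            # pose: grating orientation is free within a class
            angle = rng.uniform(0.0, np.pi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            img += (config.texture_amplitude
                    * _grating(s, freq, angle, phase)[:, :, None] * color_mix)
            deg = rng.uniform(-config.rotation_jitter_deg, config.rotation_jitter_deg)
            img = ndimage.rotate(img, deg, axes=(0, 1), reshape=False,
                                 order=1, mode="nearest")
            img *= 1.0 + rng.uniform(-config.brightness_jitter, config.brightness_jitter)
            if config.noise_sigma > 0:
                img += rng.normal(0.0, config.noise_sigma, size=img.shape)
            images[idx] = np.clip(img, 0.0, 1.0)
            labels[idx] = c
            idx += 1
    manifest = {
        "n_classes": config.n_classes,
        "image_size": s,
        "samples_per_class": config.samples_per_class,
        "n_structure_groups": config.n_structure_groups,
        "texture_params": [
            {"class": c, "freq_cycles": textures[c][0],
             "color_mix": np.asarray(textures[c][1]).tolist(),
             "structure_group": c % config.n_structure_groups}
            for c in range(config.n_classes)
        ],
        "noise_sigma": config.noise_sigma,
        "seed": config.seed,
    }
    return images, labels, manifest


@dataclass(frozen=True)
class SessionProtocol:
    """Base class list plus ordered N-way K-shot incremental sessions."""

    base_classes: tuple[int, ...]
    sessions: tuple[tuple[int, ...], ...]
    k_shot: int

    def __post_init__(self):
        seen: set[int] = set(self.base_classes)
        if len(seen) != len(self.base_classes):
            raise ValueError("duplicate base classes")
        for sess in self.sessions:
            if seen & set(sess):
                raise ValueError("session label domains must be disjoint")
            if len(set(sess)) != len(sess):
                raise ValueError("duplicate classes within a session")
            seen |= set(sess)

    @property
    def n_way(self) -> int:
        return len(self.sessions[0]) if self.sessions else 0

    def encountered(self, upto: int) -> list[int]:
        """All classes seen after ``upto`` incremental sessions."""
        out = list(self.base_classes)
        for sess in self.sessions[:upto]:
            out.extend(sess)
        return out


def make_protocol(
    n_classes: int,
    n_base: int,
    n_sessions: int,
    n_way: int,
    k_shot: int,
    seed: int = 0,
) -> SessionProtocol:
    """Randomly assign classes to the base session and N-way K-shot
    incremental sessions with pairwise-disjoint label domains."""
    if n_base < 1 or n_way < 0 or n_sessions < 0 or k_shot < 1:
        raise ValueError("protocol counts must be positive")
    if n_base + n_sessions * n_way > n_classes:
        raise ValueError(
            f"protocol needs {n_base + n_sessions * n_way} classes, "
            f"dataset has {n_classes}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4099]))
    order = rng.permutation(n_classes)
    base = tuple(int(c) for c in order[:n_base])
    sessions = tuple(
        tuple(int(c) for c in order[n_base + t * n_way : n_base + (t + 1) * n_way])
        for t in range(n_sessions)
    )
    return SessionProtocol(base_classes=base, sessions=sessions, k_shot=k_shot)


def split_train_test(
    labels: np.ndarray, train_frac: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class disjoint train/test index split (default 75/25)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 9733]))
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        cut = int(round(train_frac * len(idx)))
        cut = min(max(cut, 1), len(idx) - 1)
        train_idx.extend(idx[:cut].tolist())
        test_idx.extend(idx[cut:].tolist())
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))
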