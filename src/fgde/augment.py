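"""Domain extension: visual transforms and extended label space.

Each training image is expanded into ``N`` named variants — the original,
its high- and low-frequency fused versions, and classic photometric /
geometric augmentations — and the label space is extended in lock-step:
variant ``n`` of base class ``y`` receives the extended label
``y * N + n``.  Training on the extended label space forces the encoder to
represent each class jointly with how it deforms under each transform,
which fills otherwise unallocated regions of the embedding space.

Random crops are treated as stochastic augmentation of a variant, not as a
label-extending variant of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _resize
from skimage.transform import rotate as _rotate

from .frequency import frequency_components, fuse

__all__ = [
    "TRANSFORM_NAMES",
    "DEFAULT_TRANSFORMS",
    "TransformSet",
    "ExtendedSample",
    "extend_labels",
    "decode_label",
    "random_crop",
    "apply_transform",
    "build_extended_batch",
]

TRANSFORM_NAMES = ("identity", "high_freq_fused", "low_freq_fused", "color_jitter", "rotation")

#: default extension set: original image, both frequency-fused variants,
#: colour jitter and rotation -> N = 5
DEFAULT_TRANSFORMS = list(TRANSFORM_NAMES)


@dataclass(frozen=True)
class TransformSet:
    """Ordered, named set of label-extending transforms."""

    transforms: tuple[str, ...] = tuple(DEFAULT_TRANSFORMS)

    def __post_init__(self):
        if len(self.transforms) < 1:
            raise ValueError("transform set must contain at least one transform")
        unknown = set(self.transforms) - set(TRANSFORM_NAMES)
        if unknown:
            raise ValueError(f"unknown transforms: {sorted(unknown)}")
        object.__setattr__(self, "transforms", tuple(self.transforms))

    @property
    def n_variants(self) -> int:
        return len(self.transforms)


@dataclass
class ExtendedSample:
    """One image variant with its extended label ``y * N + n``."""

    pixels: np.ndarray
    base_label: int
    variant_index: int
    extended_label: int = field(init=False)
    n_variants: int = 1

    def __post_init__(self):
        self.extended_label = extend_labels(self.base_label, self.variant_index, self.n_variants)


def extend_labels(y: int, n: int, n_variants: int) -> int:
    """Map a (base label, variant index) pair into the extended label space."""
    if y < 0:
        raise ValueError(f"base label must be nonnegative, got {y}")
    if not (0 <= n < n_variants):
        raise ValueError(f"variant index {n} out of range [0, {n_variants})")
    return y * n_variants + n


def decode_label(extended: int, n_variants: int) -> tuple[int, int]:
    """Inverse of :func:`extend_labels`: ``extended -> (y, n)``."""
    if extended < 0:
        raise ValueError("extended label must be nonnegative")
    return divmod(extended, n_variants)


def _as_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def random_crop(
    image: np.ndarray,
    w_range: tuple[int, int],
    h_range: tuple[int, int],
    rng: np.random.Generator | int,
    out_size: tuple[int, int] | None = None,
) -> np.ndarray:
    """Random crop with uniformly drawn size and position, resized back.

    Crop width/height are drawn uniformly from the inclusive ranges, the
    top-left corner ``(x_r, y_r)`` uniformly from the valid region, and the
    bottom-right corner is ``(x_r + w_crop - 1, y_r + h_crop - 1)``.  The
    crop is resized to ``out_size`` (default: the input size), so the
    operation is shape-preserving by default.  Seeded calls are
    bit-reproducible.
    """
    image = _as_image(image)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    h, w = image.shape[:2]
    w_min, w_max = int(w_range[0]), int(w_range[1])
    h_min, h_max = int(h_range[0]), int(h_range[1])
    if w_min > w_max or h_min > h_max:
        raise ValueError("empty crop range")
    if w_max > w or h_max > h or w_min < 1 or h_min < 1:
        raise ValueError(f"crop range exceeds image dimensions {h}x{w}")
    w_crop = int(rng.integers(w_min, w_max + 1))
    h_crop = int(rng.integers(h_min, h_max + 1))
    x_r = int(rng.integers(0, w - w_crop + 1))
    y_r = int(rng.integers(0, h - h_crop + 1))
    x_f = x_r + w_crop - 1
    y_f = y_r + h_crop - 1
    crop = image[y_r : y_f + 1, x_r : x_f + 1]
    target = (h, w) if out_size is None else (int(out_size[0]), int(out_size[1]))
    if crop.shape[:2] != target:
        crop = _resize(crop, target + (3,), order=1, mode="edge", anti_aliasing=False)
    return np.clip(crop, 0.0, 1.0)


def _color_jitter(image: np.ndarray, rng: np.random.Generator, strength: float = 0.2) -> np.ndarray:
    brightness = 1.0 + rng.uniform(-strength, strength)
    contrast = 1.0 + rng.uniform(-strength, strength)
    saturation = 1.0 + rng.uniform(-strength, strength)
    out = image * brightness
    mean = out.mean()
    out = (out - mean) * contrast + mean
    gray = out.mean(axis=2, keepdims=True)
    out = gray + (out - gray) * saturation
    return np.clip(out, 0.0, 1.0)


def _rotation(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # right-angle turn plus a small free-angle jitter keeps class semantics
    k = int(rng.integers(1, 4))
    jitter = float(rng.uniform(-15.0, 15.0))
    out = np.rot90(image, k=k, axes=(0, 1))
    out = _rotate(out, jitter, mode="edge", order=1)
    return np.clip(out, 0.0, 1.0)


def apply_transform(
    name: str,
    image: np.ndarray,
    tau_cut: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply one named variant transform; output shape equals input shape."""
    image = _as_image(image)
    if name == "identity":
        return image.copy()
    if name == "high_freq_fused":
        _, high = frequency_components(image, tau_cut)
        return fuse(high, image)
    if name == "low_freq_fused":
        low, _ = frequency_components(image, tau_cut)
        return fuse(low, image)
    if name == "color_jitter":
        return _color_jitter(image, rng)
    if name == "rotation":
        return _rotation(image, rng)
    raise ValueError(f"unknown transform {name!r}")


def build_extended_batch(
    images: np.ndarray,
    labels: np.ndarray,
    transform_set: TransformSet,
    tau_cut: int,
    rng_seed: int,
) -> list[ExtendedSample]:
    """Expand a batch into ``N`` labelled variants per image.

    Variants are emitted in the fixed order of ``transform_set``; the
    output always holds ``N * len(images)`` samples.  All randomness flows
    from ``rng_seed``, so identical seeds give bit-identical batches.
    """
    labels = np.asarray(labels)
    images = np.asarray(images, dtype=np.float64)
    if len(images) != len(labels):
        raise ValueError("images and labels length mismatch")
    rng = np.random.default_rng(int(rng_seed))
    n = transform_set.n_variants
    out: list[ExtendedSample] = []
    for image, y in zip(images, labels):
        for idx, name in enumerate(transform_set.transforms):
            pixels = apply_transform(name, image, tau_cut, rng)
            out.append(
                ExtendedSample(
                    pixels=pixels, base_label=int(y), variant_index=idx, n_variants=n
                )
            )
    return out
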