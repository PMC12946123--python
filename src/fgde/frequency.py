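"""2-D DCT frequency decomposition of images.

Fine-grained plant images carry their class identity largely in
high-frequency texture detail, while global layout, pose and illumination
live in the low-frequency band.  This module splits an image into those two
bands with an orthonormal type-II 2-D discrete cosine transform and a
binary low-pass mask defined by Manhattan distance from the spectral
origin, and fuses a band back onto the original image to form the
detail-enhanced inputs consumed by the encoder.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft

__all__ = [
    "dct2",
    "idct2",
    "manhattan_mask",
    "split_spectrum",
    "frequency_components",
    "fuse",
    "default_tau_cut",
]


def _check_finite(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must have positive dimensions, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def dct2(channel: np.ndarray) -> np.ndarray:
    """Orthonormal type-II 2-D DCT of a single image channel.

    Normalisation uses ``alpha_k = sqrt(1/N)`` for ``k = 0`` and
    ``sqrt(2/N)`` otherwise, so the transform is unitary: ``idct2`` is the
    exact inverse and coefficient energy equals pixel energy (Parseval).
    Low frequencies sit near index ``(0, 0)``.
    """
    channel = _check_finite(channel, "channel")
    return _fft.dctn(channel, type=2, norm="ortho")


def idct2(spectrum: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct2` (orthonormal type-III 2-D DCT)."""
    spectrum = _check_finite(spectrum, "spectrum")
    return _fft.idctn(spectrum, type=2, norm="ortho")


def manhattan_mask(height: int, width: int, tau_cut: int) -> np.ndarray:
    """Binary low-pass mask: 1 where the index sum ``h + w <= tau_cut``.

    The complement ``1 - M`` is the matching high-pass mask.
    """
    if height < 1 or width < 1:
        raise ValueError("mask dimensions must be >= 1")
    tau_cut = int(tau_cut)
    if tau_cut < 0:
        raise ValueError(f"tau_cut must be nonnegative, got {tau_cut}")
    h = np.arange(height)[:, None]
    w = np.arange(width)[None, :]
    return ((h + w) <= tau_cut).astype(np.float64)


def split_spectrum(spectrum: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition a spectrum into low- and high-frequency parts.

    Returns ``(spectrum * M, spectrum * (1 - M))``; the two parts sum back
    to the input bit-exactly because the mask is binary.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if spectrum.shape != mask.shape:
        raise ValueError(
            f"spectrum shape {spectrum.shape} does not match mask shape {mask.shape}"
        )
    low = spectrum * mask
    high = spectrum - low
    return low, high


def default_tau_cut(height: int, width: int) -> int:
    """Default Manhattan cut-off: ``floor((H + W) / 8)``."""
    return (int(height) + int(width)) // 8


def frequency_components(image: np.ndarray, tau_cut: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel low/high frequency decomposition of an H x W x C image.

    Each channel independently goes through DCT -> mask split -> inverse
    DCT.  By linearity ``I_low + I_high`` reconstructs the image to
    floating-point precision.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
        squeeze = True
    else:
        squeeze = False
    if image.ndim != 3:
        raise ValueError(f"image must be HxW or HxWxC, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    h, w, _ = image.shape
    mask = manhattan_mask(h, w, tau_cut)
    low = np.empty_like(image)
    high = np.empty_like(image)
    for c in range(image.shape[2]):
        spec = dct2(image[:, :, c])
        lo_spec, hi_spec = split_spectrum(spec, mask)
        low[:, :, c] = idct2(lo_spec)
        high[:, :, c] = idct2(hi_spec)
    if squeeze:
        return low[:, :, 0], high[:, :, 0]
    return low, high


def fuse(component: np.ndarray, original: np.ndarray) -> np.ndarray:
    """Detail-enhancing fusion ``component * original + original``.

    The elementwise product re-weights the original image by the frequency
    component; adding the original back keeps the result anchored to the
    input.  This fused array is what the encoder consumes.
    """
    component = np.asarray(component, dtype=np.float64)
    original = np.asarray(original, dtype=np.float64)
    if component.shape != original.shape:
        raise ValueError(
            f"component shape {component.shape} does not match image shape {original.shape}"
        )
    return component * original + original
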