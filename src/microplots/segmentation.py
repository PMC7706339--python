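"""Vegetation segmentation: Excess Green index, Otsu binarization, denoising.

The Excess Green (ExG) index ``2g - r - b`` is computed on chromaticity
coordinates (each channel divided by the per-pixel channel sum), which makes
it invariant to per-pixel brightness scaling; a global max-normalization
mode is available for callers that prefer it.  The ExG map is quantized to
256 levels over its observed range and thresholded with Otsu's criterion
(maximum between-class variance, lowest level on ties).  Small connected
components — weeds and speckle — are then removed with an area opening,
controlled by the user's ``noise`` parameter in pixels.
"""

from __future__ import annotations

import numpy as np
from skimage.morphology import remove_small_objects as _skimage_remove_small

from .errors import UnsegmentableImageError

__all__ = [
    "compute_excess_green",
    "otsu_threshold",
    "binarize_excess_green",
    "remove_small_objects",
    "segment_vegetation",
]

_OTSU_LEVELS = 256


def compute_excess_green(image: np.ndarray, normalization: str = "chromaticity") -> np.ndarray:
    """Excess Green vegetation index, ``ExG = 2g - r - b``, per pixel.

    Parameters
    ----------
    image : (H, W, 3) array
        RGB image; any numeric dtype.
    normalization : {"chromaticity", "global-max"}
        ``"chromaticity"`` divides each channel by the per-pixel channel sum
        (all-zero pixels map to ExG 0); ``"global-max"`` divides all channels
        by the global maximum instead, so ExG scales with brightness.

    Returns
    -------
    (H, W) float array in [-2, 2].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    rgb = image.astype(np.float64)
    if normalization == "chromaticity":
        total = rgb.sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(total[..., None] > 0, rgb / total[..., None], 0.0)
    elif normalization == "global-max":
        peak = rgb.max()
        norm = rgb / peak if peak > 0 else rgb
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    r, g, b = norm[..., 0], norm[..., 1], norm[..., 2]
    return 2.0 * g - r - b


def _quantize(exg: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(exg.min()), float(exg.max())
    if hi <= lo:
        raise UnsegmentableImageError(
            "vegetation-index map is constant; cannot threshold")
    scaled = (exg - lo) * ((_OTSU_LEVELS - 1) / (hi - lo))
    return scaled.astype(np.int64), lo, hi


def _otsu_level(counts: np.ndarray) -> int:
    """Otsu's level on a 256-bin histogram: maximize between-class variance.

    Classes are levels ``<= k`` vs ``> k``; the lowest maximizing ``k`` wins.
    """
    counts = counts.astype(np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts)
    levels = np.arange(len(counts))
    mass0 = np.cumsum(counts * levels)
    mu_total = mass0[-1] / total
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise UnsegmentableImageError("single-level histogram; cannot threshold")
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mass0 / w0
        mu1 = (mass0[-1] - mass0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~valid] = -np.inf
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximum


def otsu_threshold(exg: np.ndarray) -> float:
    """Otsu threshold of a vegetation-index map, on the map's own scale.

    The map is quantized to 256 levels over its observed range; the returned
    value is the upper edge of the background class, so vegetation is
    ``exg > threshold``.  A constant map raises
    :class:`~microplots.errors.UnsegmentableImageError`.
    """
    exg = np.asarray(exg, dtype=np.float64)
    levels, lo, hi = _quantize(exg)
    counts = np.bincount(levels.ravel(), minlength=_OTSU_LEVELS)
    k = _otsu_level(counts)
    return lo + (k + 1) * (hi - lo) / _OTSU_LEVELS


def binarize_excess_green(exg: np.ndarray) -> np.ndarray:
    """Binarize an ExG map at its Otsu level (vegetation = True)."""
    exg = np.asarray(exg, dtype=np.float64)
    levels, _, _ = _quantize(exg)
    counts = np.bincount(levels.ravel(), minlength=_OTSU_LEVELS)
    k = _otsu_level(counts)
    return levels > k


def remove_small_objects(mask: np.ndarray, noise: int) -> np.ndarray:
    """Drop 8-connected components with area < ``noise`` pixels.

    ``noise=0`` is the identity.  Idempotent.
    """
    if noise < 0:
        raise ValueError(f"noise must be >= 0, got {noise}")
    mask = np.asarray(mask).astype(bool)
    if noise <= 1:
        return mask.copy()
    # max_size removes components with area <= value; keep area >= noise
    return _skimage_remove_small(mask, max_size=noise - 1, connectivity=2)


def segment_vegetation(image: np.ndarray, noise: int, input_type: str = "rgb",
                       normalization: str = "chromaticity") -> np.ndarray:
    """Full preprocessing: RGB -> ExG -> Otsu -> denoise, or denoise only.

    ``input_type="binary"`` skips the index/threshold steps and only removes
    small objects, for masks produced by an external segmenter.
    """
    if input_type == "rgb":
        mask = binarize_excess_green(compute_excess_green(image, normalization))
    elif input_type == "binary":
        mask = np.asarray(image) != 0
        if mask.ndim != 2:
            raise ValueError("binary input must be single-band")
    else:
        raise ValueError(f"input_type must be 'rgb' or 'binary', got {input_type!r}")
    return remove_small_objects(mask, noise)
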