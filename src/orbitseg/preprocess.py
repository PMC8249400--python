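"""Intensity normalization, CT contrast saturation, resampling, half-image
cropping, and training-time augmentation.

All operations are pure: they return new arrays and never modify their inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .types import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentConfig",
    "normalize_minmax",
    "saturate_percentiles",
    "resample_isotropic",
    "crop_half",
    "augment_pair",
]


@dataclass
class AugmentConfig:
    """On-the-fly augmentation: horizontal reflection with probability 1/2 and
    rotation by an angle drawn uniformly from +-``rotation_range_deg``."""

    flip_probability: float = 0.5
    rotation_range_deg: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.flip_probability <= 1:
            raise ValueError("flip_probability must lie in [0, 1]")
        if self.rotation_range_deg < 0:
            raise ValueError("rotation_range_deg must be >= 0")


def normalize_minmax(image: np.ndarray) -> np.ndarray:
    """Affinely map intensities onto [0, 1].

    A constant image has no defined affine map; it is sent to all zeros and a
    warning is logged, so degenerate slices never crash a batch.
    """
    image = np.asarray(image, np.float64)
    if image.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo, hi = image.min(), image.max()
    if hi == lo:
        logger.warning("normalize_minmax: constant image (value %g) mapped to zeros", lo)
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def saturate_percentiles(
    image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Clip intensities to the [``low_pct``, ``high_pct``] empirical percentiles.

    Used on the CT path feeding the global network, where sparse extreme-valued
    pixels would otherwise dominate min-max normalization and crush the usable
    contrast of the image.  Applied per slice.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    image = np.asarray(image, np.float64)
    # nearest-order-statistic percentiles make the operation exactly idempotent
    lo, hi = np.percentile(image, [low_pct, high_pct], method="nearest")
    return np.clip(image, lo, hi)


def resample_isotropic(
    volume: ImageVolume, target_spacing_mm: float = 0.5, *, is_mask: bool = False
) -> ImageVolume:
    """Resample the in-plane axes to a common isotropic spacing.

    Intensities are linearly interpolated; masks (``is_mask=True``) use
    nearest-neighbour so they stay binary.  Slice spacing is left untouched
    (the slice axis is the acquisition axis).
    """
    if volume.spacing_mm is None:
        raise ValueError("volume has no spacing metadata; cannot resample")
    sz, sr, sc = volume.spacing_mm
    factors = (1.0, sr / target_spacing_mm, sc / target_spacing_mm)
    if np.allclose(factors, 1.0):
        return ImageVolume(volume.data.copy(), (sz, target_spacing_mm, target_spacing_mm))
    order = 0 if is_mask else 1
    out = ndi.zoom(np.asarray(volume.data, np.float64), factors, order=order)
    if is_mask:
        out = out > 0.5
    return ImageVolume(out, (sz, target_spacing_mm, target_spacing_mm))


def crop_half(image: np.ndarray, side: str = "left") -> np.ndarray:
    """Keep one lateral half of a slice (the half containing the labelled orbit).

    The output has width ``floor(width / 2)``; ``side='right'`` keeps the last
    ``floor(width / 2)`` columns so both halves have equal width.
    """
    image = np.asarray(image)
    w = image.shape[-1]
    if w < 2:
        raise ValueError("image too narrow to halve")
    half = w // 2
    if side == "left":
        return image[..., :half]
    if side == "right":
        return image[..., w - half :]
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def half_offset(width: int, side: str) -> int:
    """Column offset of the cropped half within the full slice (for mapping
    half-image coordinates back to full-slice coordinates)."""
    return 0 if side == "left" else width - width // 2


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform identically to an image and its mask.

    Rotation uses bilinear interpolation for the image and nearest-neighbour
    for the mask, about the image center; out-of-frame pixels are filled with
    the image minimum to avoid creating spurious bright borders.
    """
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} must be congruent")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    # preserve float32 inputs (training batches) to avoid needless upcasts
    dtype = np.float32 if np.asarray(image).dtype == np.float32 else np.float64
    img = np.asarray(image, dtype)
    msk = np.asarray(mask)
    if rng.random() < cfg.flip_probability:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    if cfg.rotation_range_deg > 0:
        angle = rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg)
        img = ndi.rotate(img, angle, reshape=False, order=1, mode="constant", cval=img.min())
        msk = (
            ndi.rotate(
                msk.astype(np.float64), angle, reshape=False, order=0, mode="constant", cval=0
            )
            > 0.5
        )
    return img, msk
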