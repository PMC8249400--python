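"""Stage 1 post-processing: from a region probability map to an orbit center
and a fixed 128 x 128 region of interest.

The global network labels the orbital cavity coarsely; the map is binarized,
holes are filled, everything but the largest connected component is discarded,
and the component centroid becomes the proposed orbit center.  Foreground uses
8-connectivity and background (holes) 4-connectivity, the standard pairing
that keeps inside/outside consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .types import as_bool_mask

ROI_SIZE = 128

__all__ = [
    "RoiSpec",
    "fill_holes",
    "largest_component",
    "centroid",
    "extract_roi",
    "localize_orbit",
    "LocalizationResult",
]

_FOREGROUND_STRUCT = ndi.generate_binary_structure(2, 2)  # 8-connected


@dataclass(frozen=True)
class RoiSpec:
    """A fixed-size crop window in full-slice coordinates."""

    center: tuple[float, float]
    offset: tuple[int, int]  # top-left corner (row, col)
    size: int = ROI_SIZE

    def to_full(self, points: np.ndarray) -> np.ndarray:
        """Map (row, col) points from ROI coordinates back to the full slice."""
        return np.asarray(points, float) + np.asarray(self.offset, float)

    def to_roi(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) - np.asarray(self.offset, float)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill every background component not connected to the image border.

    Foreground never shrinks; idempotent.
    """
    return ndi.binary_fill_holes(as_bool_mask(mask))


def largest_component(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Keep only the largest 8-connected foreground component.

    Returns ``(component_mask, found)``; an empty input yields an empty mask
    with ``found=False`` so the pipeline can take its fallback path.  Equal
    areas tie-break on the first label in row-major scan order.
    """
    mask = as_bool_mask(mask)
    labels, n = ndi.label(mask, structure=_FOREGROUND_STRUCT)
    if n == 0:
        return np.zeros_like(mask), False
    areas = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1  # argmax takes the first maximum: scan order
    return labels == best, True


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean of the foreground pixel coordinates."""
    mask = as_bool_mask(mask)
    if not mask.any():
        raise ValueError("cannot compute the centroid of an empty mask")
    r, c = np.nonzero(mask)
    return float(r.mean()), float(c.mean())


def extract_roi(
    slice_image: np.ndarray, center: tuple[float, float], size: int = ROI_SIZE
) -> tuple[np.ndarray, RoiSpec]:
    """Crop a ``size x size`` window centered on ``center``, clamped inside
    the slice so every ROI pixel is real data."""
    rows, cols = slice_image.shape
    if rows < size or cols < size:
        raise ValueError(
            f"slice {slice_image.shape} smaller than the {size}x{size} ROI; resample first"
        )
    r0 = int(np.clip(round(center[0]) - size // 2, 0, rows - size))
    c0 = int(np.clip(round(center[1]) - size // 2, 0, cols - size))
    roi = slice_image[r0 : r0 + size, c0 : c0 + size]
    return roi, RoiSpec(center=(float(center[0]), float(center[1])), offset=(r0, c0), size=size)


@dataclass(frozen=True)
class LocalizationResult:
    center: tuple[float, float] | None
    found: bool


def localize_orbit(prob_map: np.ndarray, threshold: float = 0.5) -> LocalizationResult:
    """Threshold -> fill holes -> largest component -> centroid.

    ``threshold=0.5`` is the two-class softmax decision boundary.  An
    all-background map reports ``found=False``; the pipeline then falls back
    to the nearest previously localized slice's center.
    """
    prob_map = np.asarray(prob_map, float)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    binary = prob_map > threshold
    filled = fill_holes(binary)
    comp, found = largest_component(filled)
    if not found:
        return LocalizationResult(center=None, found=False)
    return LocalizationResult(center=centroid(comp), found=True)
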