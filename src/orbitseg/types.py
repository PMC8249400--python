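"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* images are ``(rows, cols)`` float arrays; volumes are ``(slices, rows, cols)``,
  slices ordered anterior -> posterior (the exact anatomical direction is
  irrelevant to the algorithms, only the ordering matters);
* coordinates are ``(row, col)`` with row increasing downward;
* binary masks are boolean arrays; probability maps are floats in ``[0, 1]``;
* contours are ``(n_points, 2)`` float arrays of ``(row, col)`` points forming a
  closed loop (last point connects back to the first).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: in-plane / through-plane voxel edge length, millimetres
DEFAULT_SPACING_MM = 0.5


@dataclass
class ImageVolume:
    """An ordered stack of coronal 2-D intensity slices with voxel spacing.

    Parameters
    ----------
    data:
        ``(n_slices, rows, cols)`` array of intensities.
    spacing_mm:
        ``(slice, row, col)`` voxel spacing in millimetres.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (
        DEFAULT_SPACING_MM,
        DEFAULT_SPACING_MM,
        DEFAULT_SPACING_MM,
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D (slices, rows, cols), got {self.data.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class SliceSegmentation:
    """Per-slice output of the pipeline: closed contour, filled mask, center."""

    slice_index: int
    contour: np.ndarray  # (n, 2) float (row, col)
    mask: np.ndarray  # bool, full-slice coordinates
    center: tuple[float, float] | None  # stage-1 proposed centroid, full-slice coords
    low_confidence: bool = False
    roi_offset: tuple[int, int] | None = None  # top-left corner of the 128x128 crop


@dataclass
class VolumeSegmentation:
    """Pipeline output for one volume (after slice averaging / end-slice omission)."""

    slices: list[SliceSegmentation] = field(default_factory=list)
    evaluated_indices: list[int] = field(default_factory=list)
    localization_failures: int = 0


def as_bool_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce a 0/1, 0/255 or boolean array into a boolean mask."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    if np.issubdtype(mask.dtype, np.floating):
        return mask > 0.5
    return mask > 0
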