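"""Conversions between closed contours and filled region masks."""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi
from skimage.draw import line

__all__ = ["mask_to_contour", "contour_to_mask", "boundary_ring"]


# clockwise Moore neighbourhood in image coordinates (row down), starting east
_MOORE = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))


def mask_to_contour(mask: np.ndarray, center: tuple[float, float] | None = None) -> np.ndarray:
    """Ordered closed contour of a simply connected mask.

    Moore-neighbour boundary tracing: starting at the topmost-leftmost
    foreground pixel, walk the outer border clockwise, always scanning the
    Moore neighbourhood from the last background pixel visited.  Consecutive
    contour points are 8-adjacent and the sequence closes on itself, so
    rasterizing and flood-filling the contour reproduces the mask exactly for
    hole-free regions.

    ``center`` is accepted for interface symmetry with the polar contour code
    but not needed by the tracer.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot trace the contour of an empty mask")
    pts = np.argwhere(mask)
    if len(pts) == 1:
        return pts.astype(float)
    padded = np.pad(mask, 1)
    start = tuple(np.argwhere(padded)[0])  # topmost, then leftmost
    start_back = (start[0], start[1] - 1)  # its west neighbour is background
    contour = [start]
    b, c = start, start_back
    max_steps = 4 * int(mask.sum()) + 8
    for _ in range(max_steps):
        # scan clockwise starting just after the backtrack pixel
        off = (c[0] - b[0], c[1] - b[1])
        k0 = _MOORE.index(off)
        nxt, nxt_back = None, None
        for i in range(1, 9):
            dr, dc = _MOORE[(k0 + i) % 8]
            cand = (b[0] + dr, b[1] + dc)
            if padded[cand]:
                nxt = cand
                pdr, pdc = _MOORE[(k0 + i - 1) % 8]
                nxt_back = (b[0] + pdr, b[1] + pdc)
                break
        if nxt is None:  # isolated pixel reached through a 1-px bridge
            break
        b, c = nxt, nxt_back
        if b == start and c == start_back:
            break
        contour.append(b)
    return np.asarray(contour, float) - 1.0  # undo the padding offset


def contour_to_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed contour (joining consecutive points with digital
    lines) and flood-fill the enclosed region."""
    contour = np.asarray(contour)
    if len(contour) < 3:
        raise ValueError("a closed contour needs at least 3 points")
    canvas = np.zeros(shape, bool)
    pts = np.clip(np.rint(contour).astype(int), 0, np.array(shape) - 1)
    for a, b in zip(pts, np.roll(pts, -1, axis=0)):
        rr, cc = line(a[0], a[1], b[0], b[1])
        canvas[rr, cc] = True
    return ndi.binary_fill_holes(canvas)


def boundary_ring(mask: np.ndarray, thickness: int = 1) -> np.ndarray:
    """Rasterized boundary of a filled mask, optionally dilated.

    ``thickness=1`` gives the 8-connected outline; an odd ``thickness`` of
    2k+1 dilates the ring k times with a 3x3 structuring element (used as an
    easier-to-learn stage-2 training target).
    """
    mask = np.asarray(mask, bool)
    interior = ndi.binary_erosion(
        mask, structure=ndi.generate_binary_structure(2, 1), border_value=0
    )
    ring = mask & ~interior
    if thickness > 1:
        ring = ndi.binary_dilation(
            ring, structure=ndi.generate_binary_structure(2, 2), iterations=(thickness - 1) // 2
        )
    return ring
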