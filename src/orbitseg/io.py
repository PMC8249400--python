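"""Reading and writing volumes, masks, contours and segmentation results.

Volumes are stored either as a directory of per-slice 16-bit TIFFs
(``slice_000.tif`` ...) or as a single multi-page TIFF; masks as 8-bit 0/255
TIFFs; contours as CSV with columns (slice_index, point_index, row, col).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .phantom import PhantomParams, PhantomVolume
from .types import DEFAULT_SPACING_MM, ImageVolume, VolumeSegmentation

__all__ = [
    "read_volume",
    "write_contours_csv",
    "read_contours_csv",
    "write_segmentation",
    "load_phantom",
]


def read_volume(
    path: str | Path, spacing_mm: tuple[float, float, float] | None = None
) -> ImageVolume:
    """Load a volume from a slice-series directory or a multi-page TIFF."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("slice_*.tif")) or sorted(path.glob("*.tif"))
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        data = np.stack([tifffile.imread(f) for f in files]).astype(np.float64)
        params = path / "params.yaml"
        if spacing_mm is None and params.exists():
            with open(params) as fh:
                meta = yaml.safe_load(fh)
            spacing_mm = tuple(meta.get("spacing_mm", (DEFAULT_SPACING_MM,) * 3))
    else:
        data = np.asarray(tifffile.imread(path), np.float64)
        if data.ndim == 2:
            data = data[None]
    if spacing_mm is None:
        spacing_mm = (DEFAULT_SPACING_MM,) * 3
    return ImageVolume(data, spacing_mm)


def write_contours_csv(contours: dict[int, np.ndarray], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "point_index", "row", "col"])
        for s in sorted(contours):
            for i, (r, c) in enumerate(contours[s]):
                writer.writerow([s, i, f"{r:.3f}", f"{c:.3f}"])


def read_contours_csv(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(s): g.sort_values("point_index")[["row", "col"]].to_numpy(float)
        for s, g in df.groupby("slice_index")
    }


def write_segmentation(seg: VolumeSegmentation, out_dir: str | Path) -> Path:
    """Write per-slice masks (8-bit TIFF), contours CSV and a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contours = {}
    for sl in seg.slices:
        tifffile.imwrite(out / f"pred_mask_{sl.slice_index:03d}.tif",
                         (sl.mask * 255).astype(np.uint8))
        contours[sl.slice_index] = sl.contour
    write_contours_csv(contours, out / "pred_contours.csv")
    manifest = {
        "evaluated_indices": seg.evaluated_indices,
        "localization_failures": seg.localization_failures,
        "centers": {sl.slice_index: list(sl.center) if sl.center else None for sl in seg.slices},
        "low_confidence": {sl.slice_index: sl.low_confidence for sl in seg.slices},
        "roi_offsets": {
            sl.slice_index: list(sl.roi_offset) if sl.roi_offset else None for sl in seg.slices
        },
    }
    with open(out / "segmentation.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def load_phantom(path: str | Path) -> PhantomVolume:
    """Re-assemble a phantom written by :func:`orbitseg.phantom.write_volume`."""
    path = Path(path)
    with open(path / "params.yaml") as fh:
        meta = yaml.safe_load(fh)
    spacing = tuple(meta.pop("spacing_mm", (DEFAULT_SPACING_MM,) * 3))
    meta["slice_shape"] = tuple(meta["slice_shape"])
    params = PhantomParams(**meta)
    imgs = np.stack(
        [tifffile.imread(f) for f in sorted(path.glob("slice_*.tif"))]
    ).astype(np.float64)
    masks = np.stack(
        [tifffile.imread(f) for f in sorted(path.glob("mask_*.tif"))]
    ) > 0
    contour_map = read_contours_csv(path / "contours.csv")
    contours = [contour_map[s] for s in range(len(imgs))]
    centers = np.stack([np.argwhere(m).mean(axis=0) for m in masks])
    return PhantomVolume(
        intensities=ImageVolume(imgs, spacing),
        region_masks=masks,
        contours=contours,
        centers=centers,
        params=params,
    )
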