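"""Synthetic bony-orbit phantoms for training and testing the pipeline.

The clinical scans this tool targets are coronal slice stacks in which the
orbit appears as a closed ring of bone around the orbital cavity.  The phantom
reproduces the features the pipeline actually depends on:

* a closed cross-section in every slice;
* cross-section size monotonically non-increasing away from the medial slice;
* cross-sections blending from a circle toward a rounded triangle in the
  smaller posterior slices, via ``r(theta) = r * (1 + g*t*cos(3*theta)) / (1 + g*t)``
  where ``t`` grows linearly with distance from the medial slice;
* a bright, high-contrast bone ring on a uniform background for the CT style
  (plus sparse extreme-valued pixels to exercise percentile saturation), and a
  textured, low-contrast ring for the MRI style;
* one orbit per half-image (clinical scans are bilateral but only a single
  orbit is segmented, so the network sees half-images).

Ground truth (region masks, contours, centers) is always noise-free.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import yaml

from .raster import contour_to_mask, mask_to_contour
from .types import DEFAULT_SPACING_MM, ImageVolume

__all__ = [
    "PhantomParams",
    "PhantomVolume",
    "default_params",
    "generate_volume",
    "generate_dataset",
    "contour_to_mask",
    "mask_to_contour",
    "write_volume",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and noise parameters of one synthetic orbit volume.

    Intensities are normalized levels (the writer rescales to 16-bit).  CT
    outliers emulate the extreme-valued pixels (metal, air calibration) that
    motivate 1%/99% percentile saturation; they never occur in the MRI style.
    """

    n_slices: int = 9
    slice_shape: tuple[int, int] = (128, 128)
    modality: str = "ct"
    medial_radius: float = 20.0
    taper: float = 0.92  # per-slice radius multiplier away from the medial slice
    triangularity_gain: float = 0.25
    ring_thickness: float = 3.0
    bone_intensity: float = 0.95
    cavity_intensity: float = 0.35
    background_intensity: float = 0.20
    noise_sd: float = 0.02
    outlier_fraction: float = 0.002  # CT only
    center_jitter: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 3:
            raise ValueError("n_slices must be >= 3")
        if self.modality not in ("ct", "mri"):
            raise ValueError(f"modality must be 'ct' or 'mri', got {self.modality!r}")
        if self.medial_radius <= 0:
            raise ValueError("medial_radius must be positive")
        if not 0 < self.taper <= 1:
            raise ValueError("taper must lie in (0, 1]")
        if self.triangularity_gain < 0:
            raise ValueError("triangularity_gain must be >= 0")
        if self.ring_thickness < 1:
            raise ValueError("ring_thickness must be >= 1 pixel")
        if not 0 <= self.outlier_fraction <= 0.05:
            raise ValueError("outlier_fraction must lie in [0, 0.05]")
        rows, cols = self.slice_shape
        # the orbit is centered at (rows/2, cols/4) and must stay inside the
        # left half-image, ring and jitter included
        reach = self.medial_radius + self.ring_thickness + self.center_jitter + 2
        if rows < 2 * reach or cols < 4 * reach:
            raise ValueError(
                f"slice_shape {self.slice_shape} too small to contain the orbit "
                f"(medial_radius {self.medial_radius} + ring {self.ring_thickness} "
                f"+ jitter {self.center_jitter} in the left half-image)"
            )

    @property
    def medial_index(self) -> int:
        return (self.n_slices - 1) // 2


#: modality-specific intensity presets: the CT-like ring is bright and
#: high-contrast against a uniform background; the MRI-like ring sits at much
#: lower contrast (less than half the CT Michelson ring/background contrast)
#: and is further degraded by the multiplicative texture field and noise.
_MODALITY_PRESETS = {
    "ct": dict(bone_intensity=0.95, cavity_intensity=0.35, background_intensity=0.20,
               noise_sd=0.02, outlier_fraction=0.002),
    "mri": dict(bone_intensity=0.60, cavity_intensity=0.40, background_intensity=0.32,
                noise_sd=0.05, outlier_fraction=0.0),
}


def default_params(modality: str = "ct", **overrides) -> PhantomParams:
    """PhantomParams with the intensity/noise preset of a modality style."""
    if modality not in _MODALITY_PRESETS:
        raise ValueError(f"modality must be 'ct' or 'mri', got {modality!r}")
    kwargs: dict = dict(_MODALITY_PRESETS[modality], modality=modality)
    kwargs.update(overrides)
    return PhantomParams(**kwargs)


@dataclass
class PhantomVolume:
    """A generated phantom: noisy intensities plus exact ground truth."""

    intensities: ImageVolume
    region_masks: np.ndarray  # (n_slices, rows, cols) bool
    contours: list[np.ndarray]  # per-slice (n, 2) float closed contours
    centers: np.ndarray  # (n_slices, 2) float true centers
    params: PhantomParams

    @property
    def n_slices(self) -> int:
        return self.intensities.n_slices


def _radius_profile(params: PhantomParams) -> np.ndarray:
    """Per-slice base radius: maximal at the medial slice, geometric taper outward."""
    dist = np.abs(np.arange(params.n_slices) - params.medial_index)
    return params.medial_radius * params.taper**dist


def _triangularity_profile(params: PhantomParams) -> np.ndarray:
    """Blend factor t in [0, 1]: 0 at the medial slice, 1 at the farthest slice."""
    dist = np.abs(np.arange(params.n_slices) - params.medial_index)
    far = dist.max()
    return dist / far if far > 0 else dist.astype(float)


def _cross_section_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    base_radius: float,
    gain: float,
    t: float,
) -> np.ndarray:
    """Filled star-convex region with r(theta) = r*(1 + g*t*cos 3theta)/(1 + g*t)."""
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    dr = rr - center[0]
    dc = cc - center[1]
    rho = np.hypot(dr, dc)
    theta = np.arctan2(-dr, dc)  # theta=0 along +col, CCW with row pointing down
    gt = gain * t
    r_theta = base_radius * (1.0 + gt * np.cos(3.0 * theta)) / (1.0 + gt)
    # fill 1-px rasterization notches so the region obeys the 8-connected
    # foreground / 4-connected background pairing of a closed contour
    return ndi.binary_fill_holes(rho <= r_theta)


def _mri_texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Smooth multiplicative bias-like field in roughly [0.75, 1.25].

    Together with the low ring/background contrast of the MRI preset this
    makes the boundary locally ambiguous, mimicking how soft-tissue detail
    and field inhomogeneity degrade bone delineation in T1-weighted scans.
    """
    field = ndi.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=min(shape) / 8)
    field = field / max(np.abs(field).max(), 1e-9)
    return 1.0 + 0.25 * field


def _tissue_clutter(rng: np.random.Generator, shape: tuple[int, int], n_blobs: int = 20) -> np.ndarray:
    """Additive soft-tissue detail for the MRI style.

    T1-weighted scans show muscle, fat and vasculature around the orbit while
    CT of bone is comparatively featureless; a scatter of smooth random blobs
    reproduces that clutter and makes the low-contrast boundary locally
    ambiguous the way real MRI detail does.
    """
    rows, cols = shape
    out = np.zeros(shape)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, rows), rng.uniform(0, cols)
        sy, sx = rng.uniform(2.0, 10.0, size=2)
        amp = rng.uniform(-0.2, 0.2)
        out += amp * np.exp(-(((rr - cy) / sy) ** 2 + ((cc - cx) / sx) ** 2) / 2.0)
    return out


def generate_volume(params: PhantomParams) -> PhantomVolume:
    """Generate one phantom volume with exact ground truth.

    Deterministic for a fixed ``params.seed``.  The orbit center sits in the
    left half of each slice, jittered slice-to-slice by ``center_jitter``.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.slice_shape
    radii = _radius_profile(params)
    tri = _triangularity_profile(params)

    # base center in the left half-image
    base = np.array([rows / 2.0, cols / 4.0])
    masks = np.zeros((params.n_slices, rows, cols), bool)
    images = np.zeros((params.n_slices, rows, cols), np.float64)
    centers = np.zeros((params.n_slices, 2))
    contours: list[np.ndarray] = []

    for s in range(params.n_slices):
        jitter = rng.uniform(-params.center_jitter, params.center_jitter, size=2)
        center = base + jitter
        inner = _cross_section_mask(
            (rows, cols), tuple(center), radii[s], params.triangularity_gain, tri[s]
        )
        outer = _cross_section_mask(
            (rows, cols),
            tuple(center),
            radii[s] + params.ring_thickness,
            params.triangularity_gain,
            tri[s],
        )
        ring = outer & ~inner

        img = np.full((rows, cols), params.background_intensity)
        img[inner] = params.cavity_intensity
        img[ring] = params.bone_intensity

        if params.modality == "mri":
            img *= _mri_texture(rng, (rows, cols))
            img += _tissue_clutter(rng, (rows, cols))
        img += rng.normal(0.0, params.noise_sd, (rows, cols))
        if params.modality == "ct" and params.outlier_fraction > 0:
            n_out = int(round(params.outlier_fraction * rows * cols))
            if n_out:
                idx = rng.choice(rows * cols, size=n_out, replace=False)
                vals = rng.choice([0.0, 8.0], size=n_out)  # dead and hot pixels
                img.flat[idx] = vals

        masks[s] = inner
        images[s] = img
        centers[s] = np.argwhere(inner).mean(axis=0)
        contours.append(mask_to_contour(inner, tuple(centers[s])))

    vol = ImageVolume(images, (DEFAULT_SPACING_MM,) * 3)
    return PhantomVolume(vol, masks, contours, centers, params)


def generate_dataset(
    n_subjects: int, params: PhantomParams, seed: int
) -> list[PhantomVolume]:
    """Generate a cohort of mutually distinct phantom subjects.

    Each subject perturbs the template ``params`` (medial radius +-10%,
    intensity levels +-5%, its own center jitter stream) from a seeded
    sequence, so subjects differ but the whole cohort is reproducible.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(seed)
    volumes = []
    for _ in range(n_subjects):
        sub_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        p = dataclasses.replace(
            params,
            medial_radius=params.medial_radius * sub_rng.uniform(0.9, 1.1),
            bone_intensity=params.bone_intensity * sub_rng.uniform(0.95, 1.05),
            background_intensity=params.background_intensity * sub_rng.uniform(0.95, 1.05),
            triangularity_gain=params.triangularity_gain * sub_rng.uniform(0.8, 1.2),
            seed=int(sub_rng.integers(0, 2**31 - 1)),
        )
        volumes.append(generate_volume(p))
    return volumes


def write_volume(volume: PhantomVolume, out_dir: str | Path) -> Path:
    """Write a phantom to disk: 16-bit TIFF slices, 8-bit mask TIFFs,
    contours CSV and a YAML parameter sidecar."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = volume.intensities.data
    lo, hi = data.min(), data.max()
    scaled = np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)
    for s in range(volume.n_slices):
        tifffile.imwrite(out / f"slice_{s:03d}.tif", (scaled[s] * 65535).astype(np.uint16))
        tifffile.imwrite(
            out / f"mask_{s:03d}.tif", (volume.region_masks[s] * 255).astype(np.uint8)
        )
    with open(out / "contours.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slice_index", "point_index", "row", "col"])
        for s, contour in enumerate(volume.contours):
            for i, (r, c) in enumerate(contour):
                writer.writerow([s, i, f"{r:.3f}", f"{c:.3f}"])
    params = dataclasses.asdict(volume.params)
    params["slice_shape"] = list(params["slice_shape"])
    params["spacing_mm"] = list(volume.intensities.spacing_mm)
    with open(out / "params.yaml", "w") as fh:
        yaml.safe_dump(params, fh)
    return out
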