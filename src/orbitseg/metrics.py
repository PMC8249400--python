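"""Segmentation evaluation metrics.

Dice is computed per class (orbit and background) both per slice and pooled
over the volume; the volumetric Dice pools the confusion counts across slices
before applying the formula — it is *not* the mean of per-slice Dices, and
the two genuinely differ whenever slice difficulty varies.  Distances are
reported in pixels and in millimetres (0.5 mm isotropic voxels by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .types import DEFAULT_SPACING_MM, as_bool_mask

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion_counts",
    "dice",
    "dice_from_counts",
    "volumetric_dice",
    "centroid_error",
    "boundary_mae",
    "hausdorff",
    "evaluate_volume",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = as_bool_mask(pred)
    truth = as_bool_mask(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"masks must be congruent, got {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def dice_from_counts(c: ConfusionCounts) -> float:
    """2*TP / (2*TP + FP + FN); two empty masks count as perfect agreement."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice coefficient (F1 score) of the positive class of two masks."""
    return dice_from_counts(confusion_counts(pred, truth))


def volumetric_dice(pred_volume: np.ndarray, truth_volume: np.ndarray) -> float:
    """Dice over a whole volume: confusion counts pooled across slices first,
    the formula applied once to the pooled counts."""
    pred_volume = np.asarray(pred_volume)
    truth_volume = np.asarray(truth_volume)
    if pred_volume.shape != truth_volume.shape:
        raise ValueError("volumes must be congruent")
    total = ConfusionCounts(0, 0, 0, 0)
    for p, t in zip(pred_volume, truth_volume):
        total = total + confusion_counts(p, t)
    return dice_from_counts(total)


def centroid_error(
    pred_center: tuple[float, float], true_center: tuple[float, float]
) -> float:
    """Euclidean distance between proposed and true centroids, in pixels."""
    return float(np.hypot(pred_center[0] - true_center[0], pred_center[1] - true_center[1]))


def boundary_mae(pred: np.ndarray, truth: np.ndarray, symmetric: bool = False) -> float:
    """Mean absolute boundary error in pixels.

    Default direction: for every truth point, the distance to the nearest
    predicted point, averaged (stable when contour point densities differ).
    ``symmetric=True`` averages the two directed means.
    """
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if len(pred) < 3 or len(truth) < 3:
        raise ValueError("closed contours need at least 3 points")
    d_truth = cKDTree(pred).query(truth)[0].mean()
    if not symmetric:
        return float(d_truth)
    d_pred = cKDTree(truth).query(pred)[0].mean()
    return float((d_truth + d_pred) / 2.0)


def hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point sets, in pixels."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("point sets must be non-empty")
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


@dataclass
class EvaluationReport:
    """All per-volume metrics; mm values are px values times the in-plane
    spacing."""

    spacing_mm: float
    slices_evaluated: list[int] = field(default_factory=list)
    per_slice_dice_orbit: list[float] = field(default_factory=list)
    per_slice_dice_background: list[float] = field(default_factory=list)
    volumetric_dice_orbit: float = float("nan")
    volumetric_dice_background: float = float("nan")
    centroid_errors_px: list[float] = field(default_factory=list)
    boundary_mae_px: list[float] = field(default_factory=list)
    hausdorff_px: list[float] = field(default_factory=list)

    def summary(self) -> dict:
        def mean_sd(xs):
            if not xs:
                return {"mean": float("nan"), "sd": float("nan")}
            arr = np.asarray(xs, float)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            return {"mean": float(arr.mean()), "sd": sd}

        s = self.spacing_mm
        mae = mean_sd(self.boundary_mae_px)
        hd = mean_sd(self.hausdorff_px)
        return {
            "slices_evaluated": len(self.slices_evaluated),
            "per_slice_dice_orbit": mean_sd(self.per_slice_dice_orbit),
            "per_slice_dice_background": mean_sd(self.per_slice_dice_background),
            "volumetric_dice_orbit": self.volumetric_dice_orbit,
            "volumetric_dice_background": self.volumetric_dice_background,
            "centroid_error_px": mean_sd(self.centroid_errors_px),
            "boundary_mae_px": mae,
            "boundary_mae_mm": {"mean": mae["mean"] * s, "sd": mae["sd"] * s},
            "hausdorff_px": hd,
            "hausdorff_mm": {"mean": hd["mean"] * s, "sd": hd["sd"] * s},
        }


def evaluate_volume(
    pred_masks: np.ndarray,
    truth_masks: np.ndarray,
    pred_contours: list[np.ndarray] | None = None,
    truth_contours: list[np.ndarray] | None = None,
    pred_centers: list[tuple[float, float] | None] | None = None,
    truth_centers: list[tuple[float, float]] | None = None,
    slice_indices: list[int] | None = None,
    spacing_mm: float = DEFAULT_SPACING_MM,
    roi_masks: np.ndarray | None = None,
) -> EvaluationReport:
    """Aggregate all metrics over the evaluated slices of one volume.

    ``pred_masks`` / ``truth_masks`` are congruent (n, rows, cols) stacks of
    the slices that survive end-slice omission.  When ``roi_masks`` is given
    (a congruent boolean stack), Dice is evaluated only within it — the
    128 x 128 window extracted around the orbit — so background pixels far
    from the orbit do not inflate the background Dice.
    """
    pred_masks = np.asarray(pred_masks)
    truth_masks = np.asarray(truth_masks)
    if pred_masks.shape != truth_masks.shape:
        raise ValueError("prediction and truth volumes must be congruent")
    n = pred_masks.shape[0]
    if slice_indices is None:
        slice_indices = list(range(n))
    report = EvaluationReport(spacing_mm=spacing_mm, slices_evaluated=list(slice_indices))

    pooled_orbit = ConfusionCounts(0, 0, 0, 0)
    pooled_bg = ConfusionCounts(0, 0, 0, 0)
    for i in range(n):
        p = as_bool_mask(pred_masks[i])
        t = as_bool_mask(truth_masks[i])
        if roi_masks is not None:
            window = as_bool_mask(roi_masks[i])
            p, t = p[window], t[window]
        c_orbit = confusion_counts(p, t)
        c_bg = confusion_counts(~p, ~t)
        pooled_orbit = pooled_orbit + c_orbit
        pooled_bg = pooled_bg + c_bg
        report.per_slice_dice_orbit.append(dice_from_counts(c_orbit))
        report.per_slice_dice_background.append(dice_from_counts(c_bg))
        if pred_contours is not None and truth_contours is not None:
            report.boundary_mae_px.append(boundary_mae(pred_contours[i], truth_contours[i]))
            report.hausdorff_px.append(hausdorff(pred_contours[i], truth_contours[i]))
        if pred_centers is not None and truth_centers is not None and pred_centers[i] is not None:
            report.centroid_errors_px.append(centroid_error(pred_centers[i], truth_centers[i]))
    report.volumetric_dice_orbit = dice_from_counts(pooled_orbit)
    report.volumetric_dice_background = dice_from_counts(pooled_bg)
    return report
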