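"""End-to-end orchestration: subject-level splits, per-fold two-stage
training, full-volume segmentation, and evaluation.

Subjects — never individual slices — are the unit of splitting, so no slice
from a validation or test subject can ever reach a training batch.  Each of
the k folds holds out one training subject for validation; the test subjects
are fixed across folds.  Segmentation runs either with a single fold's models
or with the ensemble (stage-2 maps binarized and majority-voted across folds;
stage-1 localization uses the first fold's model in ensemble mode).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nets
from .graphsearch import GraphSearchConfig, extract_boundary
from .localize import extract_roi, localize_orbit
from .metrics import EvaluationReport, evaluate_volume
from .phantom import PhantomParams, PhantomVolume, default_params, generate_dataset
from .postprocess import EnsembleConfig, average_adjacent_slices, majority_vote
from .preprocess import (
    AugmentConfig,
    crop_half,
    half_offset,
    normalize_minmax,
    saturate_percentiles,
)
from .raster import boundary_ring, mask_to_contour
from .types import ImageVolume, SliceSegmentation, VolumeSegmentation

logger = logging.getLogger(__name__)

__all__ = [
    "Fold",
    "PipelineConfig",
    "config_from_dict",
    "load_config",
    "desk_config",
    "make_folds",
    "build_stage1_dataset",
    "build_stage2_dataset",
    "train_fold",
    "segment_volume",
    "evaluate_against_phantom",
    "run_experiment",
]


@dataclass(frozen=True)
class Fold:
    index: int
    train_subjects: tuple[int, ...]
    val_subjects: tuple[int, ...]


def make_folds(subjects: list[int] | int, k: int = 6, seed: int = 0) -> list[Fold]:
    """k-fold assignment over training subjects: fold i validates on one
    subject and trains on the rest; every validating subject validates
    exactly once.  The seeded shuffle is reproducible."""
    if isinstance(subjects, int):
        subjects = list(range(subjects))
    if len(subjects) < k:
        raise ValueError(f"need at least k={k} training subjects, got {len(subjects)}")
    order = list(np.random.default_rng(seed).permutation(subjects))
    folds = []
    for i in range(k):
        val = (int(order[i]),)
        train = tuple(int(s) for s in order if s != order[i])
        folds.append(Fold(index=i, train_subjects=train, val_subjects=val))
    return folds


@dataclass
class PipelineConfig:
    modality: str = "ct"
    side: str = "left"
    seed: int = 0
    phantom: PhantomParams = field(default_factory=PhantomParams)
    n_train_subjects: int = 6
    n_test_subjects: int = 5
    k_folds: int = 6
    unet_stage1: nets.UNetConfig = field(default_factory=nets.UNetConfig)
    unet_stage2: nets.UNetConfig = field(default_factory=nets.UNetConfig)
    train_stage1: nets.TrainConfig = field(default_factory=nets.TrainConfig.stage1)
    train_stage2: nets.TrainConfig = field(default_factory=nets.TrainConfig.stage2)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    boundary_thickness: int = 1
    saturate_stage2: bool = False  # percentile saturation beyond the global network
    graphsearch: GraphSearchConfig = field(default_factory=GraphSearchConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)


_CONFIG_SECTIONS = {
    "phantom": PhantomParams,
    "unet_stage1": None,  # filled below (nets types)
    "unet_stage2": None,
    "train_stage1": None,
    "train_stage2": None,
    "augment": AugmentConfig,
    "graphsearch": GraphSearchConfig,
    "ensemble": EnsembleConfig,
}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a plain dict (e.g. parsed YAML).

    Unknown fields raise a :class:`ValueError` naming the offending field, so
    a typo in a config file fails loudly instead of being silently ignored.
    """
    sections = dict(_CONFIG_SECTIONS)
    sections["unet_stage1"] = sections["unet_stage2"] = nets.UNetConfig
    sections["train_stage1"] = sections["train_stage2"] = nets.TrainConfig
    valid = set(PipelineConfig.__dataclass_fields__)
    kwargs: dict = {}
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config field: {key!r}")
        if key in sections and isinstance(value, dict):
            cls = sections[key]
            allowed = set(cls.__dataclass_fields__)
            for sub in value:
                if sub not in allowed:
                    raise ValueError(f"unknown config field: {key}.{sub}")
            if key == "phantom" and "slice_shape" in value:
                value = dict(value, slice_shape=tuple(value["slice_shape"]))
            kwargs[key] = cls(**value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML file."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def desk_config(modality: str = "ct", seed: int = 0) -> PipelineConfig:
    """Desk-scale profile: small phantoms, depth-3 / 8-filter networks,
    2 folds, 30/60 training epochs — runs on one CPU in minutes."""
    return PipelineConfig(
        modality=modality,
        seed=seed,
        phantom=default_params(modality, n_slices=5, seed=seed),
        n_train_subjects=6,
        n_test_subjects=2,
        k_folds=2,
        unet_stage1=nets.UNetConfig(depth=3, base_filters=8),
        unet_stage2=nets.UNetConfig(depth=3, base_filters=8),
        train_stage1=nets.TrainConfig.stage1(epochs=30, batch_size=8, seed=seed),
        train_stage2=nets.TrainConfig.stage2(epochs=60, batch_size=8, seed=seed),
        augment=AugmentConfig(seed=seed),
        boundary_thickness=3,
        ensemble=EnsembleConfig(k=2, vote_rule=2),
    )


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def _stage1_input(image: np.ndarray, modality: str) -> np.ndarray:
    """Global-network input: percentile-saturated (CT only) then min-max
    normalized full slice."""
    if modality == "ct":
        image = saturate_percentiles(image)
    return normalize_minmax(image)


def _stage2_input(image: np.ndarray, modality: str, saturate: bool) -> np.ndarray:
    if saturate and modality == "ct":
        image = saturate_percentiles(image)
    return normalize_minmax(image)


def build_stage1_dataset(
    volumes: list[PhantomVolume], modality: str, side: str = "left"
) -> tuple[np.ndarray, np.ndarray]:
    """Half-image inputs and filled orbit-region targets for the global net."""
    xs, ys = [], []
    for vol in volumes:
        for s in range(vol.n_slices):
            img = _stage1_input(vol.intensities.data[s], modality)
            xs.append(crop_half(img, side))
            ys.append(crop_half(vol.region_masks[s], side).astype(np.int64))
    return np.stack(xs), np.stack(ys)


def build_stage2_dataset(
    volumes: list[PhantomVolume],
    modality: str,
    boundary_thickness: int = 1,
    saturate: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """ROI inputs (128 x 128 around the true center) and rasterized boundary
    targets for the local net."""
    xs, ys = [], []
    for vol in volumes:
        for s in range(vol.n_slices):
            img = _stage2_input(vol.intensities.data[s], modality, saturate)
            roi, spec = extract_roi(img, tuple(vol.centers[s]))
            r0, c0 = spec.offset
            mask_roi = vol.region_masks[s][r0 : r0 + spec.size, c0 : c0 + spec.size]
            ys.append(boundary_ring(mask_roi, boundary_thickness).astype(np.int64))
            xs.append(roi)
    return np.stack(xs), np.stack(ys)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class FoldModels:
    fold: Fold
    stage1: nets.TrainedModel
    stage2: nets.TrainedModel


def _assert_no_leak(
    fold: Fold, test_subjects: list[int], train_ids: list[int]
) -> None:
    forbidden = set(fold.val_subjects) | set(test_subjects)
    leaked = forbidden & set(train_ids)
    if leaked:  # pragma: no cover - guarded by construction
        raise AssertionError(f"validation/test subjects {leaked} leaked into training")


def train_fold(
    fold: Fold,
    train_volumes: list[PhantomVolume],
    cfg: PipelineConfig,
    test_subject_ids: list[int] | None = None,
    verbose: bool = False,
) -> FoldModels:
    """Train stage-1 and stage-2 networks for one fold."""
    _assert_no_leak(fold, test_subject_ids or [], list(fold.train_subjects))
    tr = [train_volumes[i] for i in fold.train_subjects]
    va = [train_volumes[i] for i in fold.val_subjects]

    x1, y1 = build_stage1_dataset(tr, cfg.modality, cfg.side)
    v1 = build_stage1_dataset(va, cfg.modality, cfg.side)
    m1 = nets.build_unet(cfg.unet_stage1, seed=cfg.seed * 1000 + fold.index * 2)
    t0 = time.perf_counter()
    tm1 = nets.train(
        m1, (x1, y1), v1,
        dataclasses.replace(cfg.train_stage1, seed=cfg.train_stage1.seed + fold.index),
        augment=cfg.augment, fold=fold.index, verbose=verbose,
    )
    logger.info("fold %d stage-1 trained in %.1fs (best epoch %d)",
                fold.index, time.perf_counter() - t0, tm1.best_epoch)

    x2, y2 = build_stage2_dataset(tr, cfg.modality, cfg.boundary_thickness, cfg.saturate_stage2)
    v2 = build_stage2_dataset(va, cfg.modality, cfg.boundary_thickness, cfg.saturate_stage2)
    m2 = nets.build_unet(cfg.unet_stage2, seed=cfg.seed * 1000 + fold.index * 2 + 1)
    t0 = time.perf_counter()
    tm2 = nets.train(
        m2, (x2, y2), v2,
        dataclasses.replace(cfg.train_stage2, seed=cfg.train_stage2.seed + fold.index),
        augment=cfg.augment, fold=fold.index, verbose=verbose,
    )
    logger.info("fold %d stage-2 trained in %.1fs (best epoch %d)",
                fold.index, time.perf_counter() - t0, tm2.best_epoch)
    return FoldModels(fold=fold, stage1=tm1, stage2=tm2)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _localize_slice(
    half_map: np.ndarray, col_offset: int
) -> tuple[tuple[float, float] | None, bool]:
    res = localize_orbit(half_map)
    if not res.found:
        return None, False
    return (res.center[0], res.center[1] + col_offset), True


def segment_volume(
    intensities: ImageVolume,
    models: list[FoldModels],
    cfg: PipelineConfig,
    use_ensemble: bool = True,
) -> VolumeSegmentation:
    """Segment every slice of a volume, then apply slice averaging and
    end-slice omission.

    ``use_ensemble=False`` expects a single-element ``models`` list and runs
    that fold's networks alone; with the ensemble, stage-2 maps are binarized
    and majority-voted across folds before the graph search.
    """
    if not models:
        raise ValueError("no trained models supplied")
    n = intensities.n_slices
    data = intensities.data
    width = data.shape[2]
    col_off = half_offset(width, cfg.side)

    stage1_models = [models[0].stage1] if use_ensemble else [m.stage1 for m in models]
    centers: list[tuple[float, float] | None] = []
    for s in range(n):
        half = crop_half(_stage1_input(data[s], cfg.modality), cfg.side)
        pmap = nets.predict_map(stage1_models[0], half)
        center, found = _localize_slice(pmap, col_off)
        centers.append(center if found else None)

    # fallback: nearest previously localized slice's center
    found_idx = [i for i, c in enumerate(centers) if c is not None]
    failures = n - len(found_idx)
    if not found_idx:
        logger.warning("localization failed on every slice; volume skipped")
        return VolumeSegmentation(slices=[], evaluated_indices=[], localization_failures=n)
    for i in range(n):
        if centers[i] is None:
            nearest = min(found_idx, key=lambda j: (abs(j - i), j))
            centers[i] = centers[nearest]

    slices: list[SliceSegmentation] = []
    for s in range(n):
        img2 = _stage2_input(data[s], cfg.modality, cfg.saturate_stage2)
        roi, spec = extract_roi(img2, centers[s])
        maps = [nets.predict_map(m.stage2, roi) for m in models]
        if use_ensemble and len(maps) > 1:
            ens = cfg.ensemble if cfg.ensemble.k == len(maps) else EnsembleConfig(k=len(maps))
            prob = majority_vote(np.stack(maps), ens)
            if not prob.any():
                # a member predicting below 0.5 everywhere abstains from the
                # binarized vote, which makes a strict majority unreachable;
                # degrade to the ensemble-mean probability map for this slice
                logger.warning(
                    "slice %d: empty majority vote, falling back to mean probability map", s
                )
                prob = np.mean(maps, axis=0)
        else:
            prob = maps[0]
        center_roi = spec.to_roi(np.array([centers[s]]))[0]
        contour, mask_roi, low_conf = extract_boundary(
            prob, tuple(center_roi), cfg.graphsearch, roi_spec=spec
        )
        full_mask = np.zeros(data[s].shape, bool)
        r0, c0 = spec.offset
        full_mask[r0 : r0 + spec.size, c0 : c0 + spec.size] = mask_roi
        slices.append(
            SliceSegmentation(
                slice_index=s, contour=contour, mask=full_mask,
                center=centers[s], low_confidence=low_conf, roi_offset=spec.offset,
            )
        )

    averaged, kept = average_adjacent_slices(np.stack([sl.mask for sl in slices]))
    out_slices = []
    for j, s in enumerate(kept):
        mask = averaged[j]
        base = slices[s]
        contour = mask_to_contour(mask) if mask.any() else base.contour
        out_slices.append(
            SliceSegmentation(
                slice_index=int(s), contour=contour, mask=mask,
                center=base.center, low_confidence=base.low_confidence,
                roi_offset=base.roi_offset,
            )
        )
    return VolumeSegmentation(
        slices=out_slices,
        evaluated_indices=[int(s) for s in kept],
        localization_failures=failures,
    )


def evaluate_against_phantom(
    seg: VolumeSegmentation, truth: PhantomVolume
) -> EvaluationReport:
    """Score a segmentation against phantom ground truth on the evaluated
    slices, within the 128 x 128 window around the true orbit center."""
    idx = seg.evaluated_indices
    if not seg.slices:  # total localization failure: nothing to score
        return EvaluationReport(spacing_mm=truth.intensities.spacing_mm[1])
    pred_masks = np.stack([sl.mask for sl in seg.slices])
    truth_masks = truth.region_masks[idx]
    roi_masks = np.zeros_like(truth_masks)
    for j, s in enumerate(idx):
        _, spec = extract_roi(truth.intensities.data[s], tuple(truth.centers[s]))
        r0, c0 = spec.offset
        roi_masks[j, r0 : r0 + spec.size, c0 : c0 + spec.size] = True
    return evaluate_volume(
        pred_masks,
        truth_masks,
        pred_contours=[sl.contour for sl in seg.slices],
        truth_contours=[truth.contours[s] for s in idx],
        pred_centers=[sl.center for sl in seg.slices],
        truth_centers=[tuple(truth.centers[s]) for s in idx],
        slice_indices=idx,
        spacing_mm=truth.intensities.spacing_mm[1],
        roi_masks=roi_masks,
    )


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

def run_experiment(
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
    verbose: bool = False,
    segment_per_fold: bool = True,
) -> dict:
    """Simulate, train every fold, segment the fixed test subjects per fold
    and as an ensemble, and tabulate the evaluation.

    Returns a results dict; when ``out_dir`` is given, also writes model
    checkpoints, per-epoch training logs, a summary table (one row per fold,
    a fold-mean row, an ensemble row) and the full report JSON.
    """
    rng = np.random.default_rng(cfg.seed)
    train_seed = int(rng.integers(0, 2**31 - 1))
    test_seed = int(rng.integers(0, 2**31 - 1))
    train_vols = generate_dataset(cfg.n_train_subjects, cfg.phantom, seed=train_seed)
    test_vols = generate_dataset(cfg.n_test_subjects, cfg.phantom, seed=test_seed)
    folds = make_folds(cfg.n_train_subjects, cfg.k_folds, seed=cfg.seed)
    test_ids = list(range(cfg.n_train_subjects, cfg.n_train_subjects + cfg.n_test_subjects))

    out = Path(out_dir) if out_dir is not None else None
    all_models: list[FoldModels] = []
    for fold in folds:
        ck1 = out / f"fold{fold.index}_stage1.npz" if out else None
        ck2 = out / f"fold{fold.index}_stage2.npz" if out else None
        if ck1 is not None and ck1.exists() and ck2.exists():
            logger.info("fold %d: resuming from cached checkpoints", fold.index)
            fm = FoldModels(fold, nets.load_model(ck1), nets.load_model(ck2))
        else:
            fm = train_fold(fold, train_vols, cfg, test_subject_ids=test_ids, verbose=verbose)
        all_models.append(fm)

    def _mean_report(reports: list[EvaluationReport]) -> dict:
        summaries = [r.summary() for r in reports]
        out: dict = {"n_subjects": len(summaries)}
        for key in (
            "volumetric_dice_orbit", "volumetric_dice_background",
        ):
            out[key] = float(np.mean([s[key] for s in summaries]))
        for key in (
            "per_slice_dice_orbit", "per_slice_dice_background",
            "centroid_error_px", "boundary_mae_px", "hausdorff_px",
        ):
            out[key] = float(np.mean([s[key]["mean"] for s in summaries]))
        return out

    results: dict = {"folds": [], "config_modality": cfg.modality, "leak_check": "passed"}
    if segment_per_fold:
        for fm in all_models:
            reports = []
            for tv in test_vols:
                seg = segment_volume(tv.intensities, [fm], cfg, use_ensemble=False)
                reports.append(evaluate_against_phantom(seg, tv))
            results["folds"].append({"fold": fm.fold.index, **_mean_report(reports)})

    ens_reports = []
    n_eval_slices = 0
    for tv in test_vols:
        seg = segment_volume(tv.intensities, all_models, cfg, use_ensemble=True)
        n_eval_slices += len(seg.evaluated_indices)
        ens_reports.append(evaluate_against_phantom(seg, tv))
    results["ensemble"] = _mean_report(ens_reports)
    results["n_evaluated_slices"] = n_eval_slices
    if results["folds"]:
        fold_keys = [k for k in results["folds"][0] if k != "fold"]
        results["fold_mean"] = {
            k: float(np.mean([f[k] for f in results["folds"]])) for k in fold_keys
        }
    else:
        results["fold_mean"] = {}

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        for fm in all_models:
            nets.save_model(fm.stage1, out / f"fold{fm.fold.index}_stage1.npz")
            nets.save_model(fm.stage2, out / f"fold{fm.fold.index}_stage2.npz")
            pd.DataFrame(fm.stage1.log).to_csv(
                out / f"fold{fm.fold.index}_stage1_log.csv", index=False)
            pd.DataFrame(fm.stage2.log).to_csv(
                out / f"fold{fm.fold.index}_stage2_log.csv", index=False)
        rows = [{"row": f"fold {f['fold']}", **{k: v for k, v in f.items() if k != "fold"}}
                for f in results["folds"]]
        if results["fold_mean"]:
            rows.append({"row": "fold mean", **results["fold_mean"]})
        rows.append({"row": "ensemble", **results["ensemble"]})
        pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2)
    return results
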