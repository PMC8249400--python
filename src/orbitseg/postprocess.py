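"""Volume-level smoothing and k-fold ensemble voting.

The orbit cross-section shrinks monotonically away from the medial slice, so
an isolated over- or under-segmentation on one slice disagrees with both of
its neighbours.  Averaging each slice's mask with its predecessor and
successor (a pixel-wise 2-of-3 vote) removes such outliers; the first and
last slices, lacking one neighbour each, are omitted from further analysis.

The k cross-validation fold models form an ensemble by per-pixel majority
vote over their binarized prediction maps; the voted map is then segmented
once by the graph search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import as_bool_mask

__all__ = ["EnsembleConfig", "average_adjacent_slices", "majority_vote"]


@dataclass(frozen=True)
class EnsembleConfig:
    """``vote_rule`` is the minimum number of positive votes for a positive
    pixel; the default is a strict majority, ceil((k+1)/2) = 4 for k = 6."""

    k: int = 6
    vote_rule: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        rule = self.resolved_vote_rule
        if not 1 <= rule <= self.k:
            raise ValueError(f"vote_rule {rule} must lie in [1, k={self.k}]")

    @property
    def resolved_vote_rule(self) -> int:
        return self.vote_rule if self.vote_rule is not None else (self.k + 2) // 2


def average_adjacent_slices(masks: np.ndarray | list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise 2-of-3 vote of each interior slice with its two neighbours.

    Returns ``(averaged_masks, kept_indices)`` where ``kept_indices`` are the
    interior slice indices of the input (the first and last slices are
    dropped), so ``len(averaged) == len(masks) - 2``.
    """
    masks = np.asarray([as_bool_mask(m) for m in masks])
    if masks.ndim != 3:
        raise ValueError("expected a (n_slices, rows, cols) mask stack")
    if masks.shape[0] < 3:
        raise ValueError("slice averaging needs at least 3 slices")
    votes = masks[:-2].astype(np.int8) + masks[1:-1] + masks[2:]
    averaged = votes >= 2  # mean of three binary masks thresholded at 0.5
    kept = np.arange(1, masks.shape[0] - 1)
    return averaged, kept


def majority_vote(maps: np.ndarray | list[np.ndarray], cfg: EnsembleConfig | None = None) -> np.ndarray:
    """Per-pixel majority vote over k binarized prediction maps.

    ``maps`` may be probability maps (binarized here at 0.5) or binary masks.
    A pixel is positive when at least ``vote_rule`` models vote for it.
    """
    stack = np.asarray(maps, float)
    if stack.ndim != 3:
        raise ValueError("expected k congruent 2-D maps")
    k = stack.shape[0]
    if cfg is None:
        cfg = EnsembleConfig(k=k)
    if cfg.k != k:
        raise ValueError(f"config expects k={cfg.k} maps, got {k}")
    votes = (stack > 0.5).sum(axis=0)
    return (votes >= cfg.resolved_vote_rule).astype(float)
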