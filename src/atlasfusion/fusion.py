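"""Per-voxel atlas ranking, exponential-decay weighting and joint fusion.

At every voxel the atlases are ranked by their local similarity to the target
(rank 0 = most similar) and weighted ``w = exp(-beta * rank)``.  One weight
field drives both the intensity fusion (weighted mean of the propagated atlas
CTs, yielding the pseudo-CT) and the label fusion (normalised weighted vote),
which is what guarantees that the synthesised density and the fused labels
agree voxel by voxel.

``beta`` decays across pipeline iterations: early on, registration is still
poor and only the best-matching atlas should speak; as alignment improves a
smaller ``beta`` lets more atlases contribute to the average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import CategoricalSegVolume, ImageGrid, ProbSegVolume, ScalarVolume
from .similarity import SimilarityVolume

__all__ = [
    "RankField",
    "WeightField",
    "beta_schedule",
    "rank_atlases",
    "weights_from_ranks",
    "fuse_intensity",
    "fuse_labels",
    "categorical_from_prob",
    "votes_from_seg",
]

BETA_START = 1.0
BETA_DECREMENT = 0.125
BETA_FLOOR = 0.125
AIR_HU = -1000.0


def beta_schedule(t: int, start: float = BETA_START, decrement: float = BETA_DECREMENT, floor: float = BETA_FLOOR) -> float:
    """Decay schedule ``beta_t = start - decrement * (t - 1)``, floored.

    With the defaults: 1.0 at the first iteration, 0.875 at the second, ...
    The floor keeps the weights a strictly decreasing function of rank even
    if the pipeline is run past the point where the linear decay would reach
    zero.
    """
    if not isinstance(t, (int, np.integer)) or t < 1:
        raise ValueError("iteration index must be an integer >= 1")
    return max(start - decrement * (t - 1), floor)


@dataclass
class RankField:
    """Per-voxel rank of each atlas (0 = most similar; -1 = excluded)."""

    grid: ImageGrid
    ranks: np.ndarray  # (N, x, y, z) int
    valid: np.ndarray  # (N, x, y, z) bool, atlas contributes at voxel
    fusable: np.ndarray  # (x, y, z) bool, >= 1 atlas contributes


@dataclass
class WeightField:
    """Nonnegative per-voxel fusion weight per atlas; max weight 1 where fusable."""

    grid: ImageGrid
    weights: np.ndarray  # (N, x, y, z)
    fusable: np.ndarray


def rank_atlases(lsims: list[SimilarityVolume]) -> RankField:
    """Rank atlases by descending local similarity at every voxel.

    Atlases with ``-inf`` similarity (outside their propagated FOV) receive no
    rank and will get zero weight.  Ties break toward the lower atlas index,
    making the ranking deterministic under atlas reordering only up to ties.
    """
    if not lsims:
        raise ValueError("need at least one atlas")
    grid = lsims[0].grid
    stack = np.stack([s.values for s in lsims], axis=0)
    valid = np.stack([s.valid for s in lsims], axis=0)
    n = stack.shape[0]
    order = np.argsort(-stack, axis=0, kind="stable")  # descending, ties -> lower index first
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n).reshape((n,) + (1,) * (stack.ndim - 1)), axis=0)
    ranks = np.where(valid, ranks, -1)
    fusable = valid.any(axis=0)
    return RankField(grid, ranks, valid, fusable)


def weights_from_ranks(ranks: RankField, beta: float) -> WeightField:
    """Exponential decay of rank: ``w = exp(-beta * r)``; excluded atlases get 0."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    w = np.where(ranks.valid, np.exp(-beta * np.maximum(ranks.ranks, 0)), 0.0)
    return WeightField(ranks.grid, w, ranks.fusable)


def _fill_unfusable(values: np.ndarray, fusable: np.ndarray, body_mask: np.ndarray | None) -> np.ndarray:
    """Unfusable voxels: air outside the body, nearest fusable value inside."""
    if fusable.all():
        return values
    out = values.copy()
    holes = ~fusable
    if body_mask is not None:
        inside = holes & body_mask
        out[holes & ~body_mask] = AIR_HU
    else:
        inside = holes
    if inside.any():
        if fusable.any():
            _, idx = ndimage.distance_transform_edt(~fusable, return_indices=True)
            out[inside] = values[tuple(i[inside] for i in idx)]
        else:
            out[inside] = AIR_HU
    return out


def fuse_intensity(
    weights: WeightField,
    cts: list[ScalarVolume],
    body_mask: np.ndarray | None = None,
) -> ScalarVolume:
    """Weighted-mean fusion of propagated atlas CTs into a pseudo-CT (HU)."""
    if len(cts) != weights.weights.shape[0]:
        raise ValueError("one CT per atlas weight required")
    w = weights.weights
    num = np.zeros(weights.grid.shape, dtype=np.float64)
    den = np.zeros_like(num)
    for k, ct in enumerate(cts):
        num += w[k] * ct.values.astype(np.float64)
        den += w[k]
    fused = np.where(weights.fusable, num / np.where(den > 0, den, 1.0), 0.0)
    fused = _fill_unfusable(fused, weights.fusable, body_mask)
    return ScalarVolume(weights.grid, fused, np.ones(weights.grid.shape, bool), "pCT")


def votes_from_seg(seg: ProbSegVolume, one_hot: bool = True) -> np.ndarray:
    """Vote field for one propagated atlas segmentation.

    The default reads the propagated labels as a categorical indicator (one
    vote for the carried label); the optional fuzzy mode uses the propagated
    probabilities themselves as fractional votes.
    """
    if one_hot:
        labels = seg.argmax_labels()
        votes = np.zeros(seg.probabilities.shape, dtype=np.float32)
        idx = np.indices(labels.shape)
        votes[idx[0], idx[1], idx[2], labels] = 1.0
        return votes
    return seg.probabilities.astype(np.float32)


def fuse_labels(
    weights: WeightField,
    votes: list[np.ndarray],
    require_one_hot: bool = False,
) -> ProbSegVolume:
    """Normalised weighted voting into a probabilistic segmentation.

    Output probabilities sum to one at every fusable voxel; unfusable voxels
    become pure background.
    """
    if len(votes) != weights.weights.shape[0]:
        raise ValueError("one vote field per atlas weight required")
    n_labels = votes[0].shape[-1]
    acc = np.zeros(weights.grid.shape + (n_labels,), dtype=np.float64)
    for k, v in enumerate(votes):
        if v.shape[-1] != n_labels:
            raise ValueError("vote fields disagree on label count")
        if require_one_hot:
            flat = np.asarray(v)
            if not np.all((flat == 0) | (flat == 1)) or not np.allclose(flat.sum(axis=-1), 1.0):
                raise ValueError("vote field is not one-hot")
        acc += weights.weights[k][..., None] * v
    total = acc.sum(axis=-1)
    fusable = weights.fusable & (total > 0)
    probs = np.where(fusable[..., None], acc / np.where(total > 0, total, 1.0)[..., None], 0.0)
    probs[~fusable, 0] = 1.0
    return ProbSegVolume(weights.grid, probs.astype(np.float32))


def categorical_from_prob(seg: ProbSegVolume) -> CategoricalSegVolume:
    """Per-voxel argmax label; ties break toward the lower label index."""
    return CategoricalSegVolume(seg.grid, seg.argmax_labels().astype(np.int32))
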