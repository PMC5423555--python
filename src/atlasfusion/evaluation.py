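"""Segmentation and CT-synthesis accuracy metrics.

Fuzzy Dice between probabilistic segmentations, the modified Hausdorff
distance between segmentation boundaries (in mm), mean absolute / mean error
of a pseudo-CT against a reference CT within a region of interest, normalised
mutual information as a registration-quality surrogate, and the water-only
pseudo-CT baseline (uniform 0 HU body) that anchors how much of the synthesis
error is explained by simply knowing the body outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .image_model import GridMismatchError, ImageGrid, ProbSegVolume, ScalarVolume

__all__ = [
    "BoundaryPointSet",
    "fuzzy_dice",
    "extract_boundary",
    "modified_hausdorff",
    "mae_me",
    "nmi",
    "water_only_pct",
    "body_mask_from_ct",
]

AIR_HU = -1000.0
#: body-contour threshold on calibrated HU; the alternative +500 convention
#: (offset-intensity CTs) can be passed explicitly.
BODY_THRESHOLD_HU = -500.0


def fuzzy_dice(manual: ProbSegVolume, auto: ProbSegVolume, label: int) -> float:
    """Fuzzy set Dice ``2 sum min(p, q) / sum (p + q)`` for one label.

    Reduces to the hard voxel-count Dice on one-hot inputs.  Returns NaN when
    the label is absent from both segmentations (undefined overlap).
    """
    if not manual.grid.same_grid(auto.grid):
        raise GridMismatchError("fuzzy_dice requires a shared grid")
    p = manual.probabilities[..., label].astype(np.float64)
    q = auto.probabilities[..., label].astype(np.float64)
    den = p.sum() + q.sum()
    if den == 0:
        return float("nan")
    return float(2.0 * np.minimum(p, q).sum() / den)


@dataclass
class BoundaryPointSet:
    """Physical (mm) centres of the surface voxels of a binary mask."""

    points: np.ndarray  # (N, 3) mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)


def extract_boundary(mask: np.ndarray, grid: ImageGrid) -> BoundaryPointSet:
    """Mask voxels with a face-adjacent (6-connectivity) background neighbour.

    Voxels touching the volume edge count as boundary (outside the volume is
    background).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    boundary = mask & ~interior
    idx = np.argwhere(boundary)
    return BoundaryPointSet(grid.voxel_to_world(idx))


def modified_hausdorff(A: BoundaryPointSet, B: BoundaryPointSet) -> float:
    """max of the two directed mean nearest-neighbour distances, in mm."""
    if len(A) == 0 or len(B) == 0:
        raise ValueError("boundary point sets must be nonempty")
    da = cKDTree(B.points).query(A.points)[0]
    db = cKDTree(A.points).query(B.points)[0]
    return float(max(da.mean(), db.mean()))


def mae_me(pct: ScalarVolume, ref: ScalarVolume, roi: np.ndarray) -> tuple[float, float]:
    """Mean absolute error and mean (signed) error in HU over the ROI voxels."""
    if not pct.grid.same_grid(ref.grid):
        raise GridMismatchError("mae_me requires a shared grid")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    diff = pct.values.astype(np.float64)[roi] - ref.values.astype(np.float64)[roi]
    return float(np.abs(diff).mean()), float(diff.mean())


def nmi(I: ScalarVolume, J: ScalarVolume, bins: int = 64) -> float:
    """Normalised mutual information ``(H(I) + H(J)) / H(I, J)`` over joint FOV.

    Always >= 1; equals 2 for identical images (with more than one occupied
    bin) and tends to 1 for independent images.  Returns NaN for degenerate
    single-bin inputs.
    """
    if not I.grid.same_grid(J.grid):
        raise GridMismatchError("nmi requires a shared grid")
    omega = I.fov & J.fov
    if not omega.any():
        raise ValueError("empty joint FOV")
    a = I.values[omega].astype(np.float64)
    b = J.values[omega].astype(np.float64)
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    if np.count_nonzero(px) < 2 or np.count_nonzero(py) < 2:
        return float("nan")

    def ent(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    return (ent(px) + ent(py)) / ent(pxy.ravel())


def body_mask_from_ct(ct: ScalarVolume, threshold_hu: float = BODY_THRESHOLD_HU) -> np.ndarray:
    """Body contour: threshold, keep the largest component, fill 3-D holes."""
    mask = (ct.values > threshold_hu) & ct.fov
    if not mask.any():
        raise ValueError("empty body mask at this threshold")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def water_only_pct(ref_ct: ScalarVolume, threshold_hu: float = BODY_THRESHOLD_HU, fill_hu: float = 0.0) -> ScalarVolume:
    """Water-only baseline pseudo-CT: hole-filled body at ``fill_hu``, air outside.

    On calibrated HU the default body threshold is -500; images stored with a
    +1000 offset can pass the literal +500 convention instead.
    """
    body = body_mask_from_ct(ref_ct, threshold_hu)
    vals = np.where(body, fill_hu, AIR_HU).astype(np.float32)
    return ScalarVolume(ref_ct.grid, vals, np.ones(ref_ct.grid.shape, bool), "pCT")
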