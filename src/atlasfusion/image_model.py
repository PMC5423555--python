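"""Geometric image model, NIfTI I/O and preprocessing primitives.

All volumes live on an :class:`ImageGrid` (0-based voxel indices; physical
coordinates in mm through origin / spacing / direction cosines).  Every
intensity volume carries its own field-of-view mask ``fov`` marking where the
image actually contains data — MR and CT acquisitions of the same subject
routinely cover different physical extents, and downstream similarity measures
must know where data is missing rather than treat padding as signal.

Inter-volume arithmetic requires volumes to share a grid (within a relative
tolerance) or an explicit spatial transform; nothing here resamples silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "ProbSegVolume",
    "CategoricalSegVolume",
    "AtlasRecord",
    "AtlasDatabase",
    "LabelDictionary",
    "FormatError",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "left_right_flip",
    "bias_correction_hook",
    "DEFAULT_LABELS",
]

GRID_RTOL = 1e-5

#: Interpolation name -> spline order used by scipy.ndimage.
_INTERP_ORDER = {"nearest": 0, "linear": 1, "cubic_spline": 3}


class FormatError(ValueError):
    """Raised for malformed image files or invalid geometric metadata."""


class GridMismatchError(ValueError):
    """Raised when an operation requires two volumes to share a grid."""


@dataclass(frozen=True)
class ImageGrid:
    """Regular 3-D sampling grid: shape, spacing (mm), origin (mm), direction.

    ``direction`` is the 3x3 matrix of axis direction cosines (columns are the
    physical directions of the voxel axes).  Physical position of voxel index
    ``i`` is ``origin + direction @ (spacing * i)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise FormatError(f"grid must be 3-D, got shape {self.shape}")
        if any(s <= 0 for s in self.spacing) or not np.all(np.isfinite(self.spacing)):
            raise FormatError(f"spacing must be positive and finite, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        object.__setattr__(self, "direction", tuple(float(s) for s in self.direction))

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float).reshape(3, 3)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical-mm homogeneous affine."""
        aff = np.eye(4)
        aff[:3, :3] = self.direction_matrix @ np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map an (..., 3) array of voxel indices to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ (self.direction_matrix @ np.diag(self.spacing)).T + np.asarray(self.origin)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.direction_matrix @ np.diag(self.spacing))
        return (pts - np.asarray(self.origin)) @ inv.T

    def same_grid(self, other: "ImageGrid", rtol: float = GRID_RTOL) -> bool:
        if self.shape != other.shape:
            return False
        for a, b in ((self.spacing, other.spacing), (self.origin, other.origin), (self.direction, other.direction)):
            if not np.allclose(a, b, rtol=rtol, atol=rtol):
                return False
        return True


def _require_same_grid(a: "ImageGrid", b: "ImageGrid", what: str = "operation") -> None:
    if not a.same_grid(b):
        raise GridMismatchError(f"{what} requires volumes on the same grid")


@dataclass
class ScalarVolume:
    """A 3-D intensity image with its field-of-view mask.

    CT-like modalities ("CT", "pCT") are in Hounsfield units (air ~ -1000,
    water ~ 0); MR modalities are in arbitrary scanner units.
    """

    grid: ImageGrid
    values: np.ndarray
    fov: np.ndarray | None = None
    modality: str = "T2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(f"ScalarVolume payload must be 3-D, got {self.values.ndim}-D")
        if tuple(self.values.shape) != self.grid.shape:
            raise FormatError("values shape does not match grid shape")
        if self.fov is None:
            self.fov = np.ones(self.grid.shape, dtype=bool)
        else:
            self.fov = np.asarray(self.fov).astype(bool)
            if self.fov.shape != self.values.shape:
                raise FormatError("FOV mask shape does not match values")
        if not np.all(np.isfinite(self.values[self.fov])):
            raise FormatError("non-finite values inside the FOV")

    def copy(self, **overrides) -> "ScalarVolume":
        kw = dict(grid=self.grid, values=self.values.copy(), fov=self.fov.copy(), modality=self.modality)
        kw.update(overrides)
        return ScalarVolume(**kw)


@dataclass
class ProbSegVolume:
    """Per-voxel label-probability image; last axis indexes the L labels.

    Label 0 is background.  Probabilities sum to one per voxel (within 1e-6);
    a one-hot volume is a valid categorical encoding.
    """

    grid: ImageGrid
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float32)
        if self.probabilities.ndim != 4:
            raise FormatError("ProbSegVolume payload must be (x, y, z, L)")
        if tuple(self.probabilities.shape[:3]) != self.grid.shape:
            raise FormatError("probabilities shape does not match grid shape")
        sums = self.probabilities.sum(axis=-1)
        if np.any(self.probabilities < -1e-7) or not np.allclose(sums, 1.0, atol=1e-5):
            raise FormatError("per-voxel probabilities must be nonnegative and sum to 1")

    @property
    def n_labels(self) -> int:
        return self.probabilities.shape[-1]

    @classmethod
    def from_labels(cls, grid: ImageGrid, labels: np.ndarray, n_labels: int) -> "ProbSegVolume":
        """One-hot encode an integer label map."""
        labels = np.asarray(labels)
        if labels.max(initial=0) >= n_labels:
            raise FormatError("label index exceeds declared label count")
        probs = np.zeros(labels.shape + (n_labels,), dtype=np.float32)
        idx = np.indices(labels.shape)
        probs[idx[0], idx[1], idx[2], labels] = 1.0
        return cls(grid, probs)

    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.probabilities, axis=-1)

    def is_one_hot(self, atol: float = 1e-6) -> bool:
        p = self.probabilities
        return bool(np.all((np.abs(p) < atol) | (np.abs(p - 1.0) < atol)))

    def copy(self) -> "ProbSegVolume":
        return ProbSegVolume(self.grid, self.probabilities.copy())


@dataclass
class CategoricalSegVolume:
    """Integer label map (0 = background)."""

    grid: ImageGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)
        if tuple(self.labels.shape) != self.grid.shape:
            raise FormatError("labels shape does not match grid shape")


#: Default pelvic label dictionary.  Indices are a package convention; the
#: organ set is the one contoured for prostate radiotherapy planning.
DEFAULT_LABELS = {
    "background": 0,
    "prostate": 1,
    "bladder": 2,
    "rectum": 3,
    "femur_head_left": 4,
    "femur_head_right": 5,
    "body": 6,
}

_LATERAL_TOKENS = ("left", "right", "_l", "_r", "l_", "r_")


@dataclass
class LabelDictionary:
    """Organ-name <-> label-index mapping with declared left/right homologues."""

    names: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))
    lr_pairs: tuple[tuple[int, int], ...] = ((4, 5),)

    @property
    def n_labels(self) -> int:
        return max(self.names.values()) + 1

    def index(self, name: str) -> int:
        return self.names[name]

    def name(self, index: int) -> str:
        for k, v in self.names.items():
            if v == index:
                return k
        raise KeyError(index)

    def validate_laterality(self) -> None:
        """Every lateralised organ name must appear in an lr pair."""
        paired = {i for pair in self.lr_pairs for i in pair}
        for name, idx in self.names.items():
            low = name.lower()
            if any(tok in low for tok in ("left", "right")) and idx not in paired:
                raise ValueError(f"lateralised label '{name}' has no declared left/right homologue")

    def flip_permutation(self) -> np.ndarray:
        perm = np.arange(self.n_labels)
        for a, b in self.lr_pairs:
            perm[a], perm[b] = perm[b], perm[a]
        return perm

    def to_yaml_dict(self) -> dict:
        return {"names": dict(self.names), "lr_pairs": [list(p) for p in self.lr_pairs]}

    @classmethod
    def from_yaml_dict(cls, d: dict) -> "LabelDictionary":
        return cls(names=dict(d["names"]), lr_pairs=tuple(tuple(p) for p in d.get("lr_pairs", ())))

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_yaml_dict(), fh)

    @classmethod
    def load(cls, path) -> "LabelDictionary":
        import yaml

        with open(path) as fh:
            return cls.from_yaml_dict(yaml.safe_load(fh))


@dataclass
class AtlasRecord:
    """One subject's co-registered {T2, T1, CT, segmentation} set."""

    id: str
    t2: ScalarVolume
    t1: ScalarVolume
    ct: ScalarVolume
    seg: ProbSegVolume
    flipped: bool = False
    provenance: str = "initial"
    #: alignment transforms that produced the co-registered channels
    #: (e.g. {"t1": T1->T2 mapping, "ct": CT->T2 mapping}); audit metadata only
    transforms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for vol in (self.t1, self.ct):
            _require_same_grid(self.t2.grid, vol.grid, "AtlasRecord")
        _require_same_grid(self.t2.grid, self.seg.grid, "AtlasRecord")

    @property
    def grid(self) -> ImageGrid:
        return self.t2.grid


@dataclass
class AtlasDatabase:
    """Ordered atlas collection sharing one label dictionary."""

    records: list[AtlasRecord]
    labels: LabelDictionary = field(default_factory=LabelDictionary)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate atlas record ids")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AtlasRecord]:
        return iter(self.records)

    def exclude_subject(self, subject_id: str) -> "AtlasDatabase":
        """Drop a subject and any record derived from it (e.g. its flipped twin)."""
        base = subject_id.removesuffix("_flip")
        keep = [r for r in self.records if r.id.removesuffix("_flip") != base]
        return AtlasDatabase(records=keep, labels=self.labels)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _grid_from_affine(shape: Sequence[int], affine: np.ndarray) -> ImageGrid:
    lin = affine[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise FormatError("non-finite or non-positive voxel spacing in affine")
    direction = lin / spacing
    return ImageGrid(tuple(int(s) for s in shape), tuple(spacing), tuple(affine[:3, 3]), tuple(direction.ravel()))


def read_volume(path: str | Path, modality: str = "T2") -> ScalarVolume:
    """Read a 3-D NIfTI-1 volume; picks up a ``<stem>_fov.nii.gz`` sidecar mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3-D payload, got {data.ndim}-D in {path.name}")
    grid = _grid_from_affine(data.shape, img.affine)
    fov = None
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    for ext in (".nii.gz", ".nii"):
        cand = path.parent / f"{stem}_fov{ext}"
        if cand.exists():
            fov = np.asanyarray(nib.load(str(cand)).dataobj) > 0.5
            break
    return ScalarVolume(grid, np.ascontiguousarray(data, dtype=np.float32), fov, modality)


def write_volume(vol: ScalarVolume, path: str | Path, with_fov: bool = True) -> None:
    """Write a volume (and its FOV sidecar unless the FOV is all-ones)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.grid.affine)
    nib.save(img, str(path))
    if with_fov and not vol.fov.all():
        stem = path.name
        for suf in (".nii.gz", ".nii"):
            if stem.endswith(suf):
                stem = stem[: -len(suf)]
                ext = suf
                break
        nib.save(nib.Nifti1Image(vol.fov.astype(np.uint8), vol.grid.affine), str(path.parent / f"{stem}_fov{ext}"))


# ---------------------------------------------------------------------------
# Preprocessing


def resample_isotropic(
    vol: ScalarVolume, target_spacing_mm: float, interpolation: str = "cubic_spline"
) -> ScalarVolume:
    """Resample to an isotropic grid covering the input physical extent.

    Cubic spline is the default (the standard choice when bringing anisotropic
    MR acquisitions to isotropic resolution); the FOV mask is resampled
    nearest-neighbour and re-binarised.
    """
    if not target_spacing_mm > 0:
        raise ValueError("target spacing must be positive")
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = _INTERP_ORDER[interpolation]
    g = vol.grid
    extent = np.array(g.shape) * np.array(g.spacing)
    new_shape = tuple(int(max(1, np.ceil(e / target_spacing_mm - 1e-9))) for e in extent)
    new_grid = ImageGrid(new_shape, (target_spacing_mm,) * 3, g.origin, g.direction)
    # voxel centres of the new grid expressed in input voxel coordinates
    scale = np.array([target_spacing_mm / s for s in g.spacing])
    coords = np.indices(new_shape, dtype=float)
    for ax in range(3):
        coords[ax] *= scale[ax]
    vals = ndimage.map_coordinates(vol.values.astype(float), coords, order=order, mode="nearest")
    fov = ndimage.map_coordinates(vol.fov.astype(np.uint8), coords, order=0, mode="constant", cval=0) > 0.5
    vals = np.where(fov, vals, 0.0)
    return ScalarVolume(new_grid, vals.astype(np.float32), fov, vol.modality)


def left_right_flip(record: AtlasRecord, labels: LabelDictionary) -> AtlasRecord:
    """Mirror a record about the mid-sagittal grid plane, swapping L/R labels.

    Doubles the effective atlas count when applied across a database; paired
    lateral organs (femur heads) exchange indices so the flipped segmentation
    remains anatomically labelled.
    """
    labels.validate_laterality()
    perm = labels.flip_permutation()

    def flip_scalar(v: ScalarVolume) -> ScalarVolume:
        return ScalarVolume(v.grid, v.values[::-1].copy(), v.fov[::-1].copy(), v.modality)

    probs = record.seg.probabilities[::-1][..., perm].copy()
    return AtlasRecord(
        id=record.id.removesuffix("_flip") if record.flipped else record.id + "_flip",
        t2=flip_scalar(record.t2),
        t1=flip_scalar(record.t1),
        ct=flip_scalar(record.ct),
        seg=ProbSegVolume(record.seg.grid, probs),
        flipped=not record.flipped,
        provenance=record.provenance,
    )


def bias_correction_hook(
    vol: ScalarVolume, corrector: Callable[[ScalarVolume], ScalarVolume] | None = None
) -> ScalarVolume:
    """Pluggable slot for intensity non-uniformity correction.

    The correction algorithm itself is external; callers supply a
    volume -> volume function (e.g. wrapping an N4 implementation).  The
    default is the identity.
    """
    if corrector is None:
        return vol
    out = corrector(vol)
    if not isinstance(out, ScalarVolume) or not out.grid.same_grid(vol.grid):
        raise GridMismatchError("bias corrector must return a ScalarVolume on the input grid")
    return out
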