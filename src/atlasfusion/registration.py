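"""Multi-channel deformable registration: contract and reference backend.

The registration contract is a symmetric global (affine) stage followed by a
dense non-rigid stage driven by a weighted sum of channel costs: local
normalised cross-correlation (LNCC) for intensity channels and the
Kullback-Leibler divergence (KLD) for probabilistic segmentation channels,
optimised coarse-to-fine over an image pyramid.

The reference backend is a modest free-form optimiser adequate for
phantom-scale volumes: intensity channels are locally standardised (so that
sum-of-squares forces on the standardised images ascend the LNCC), the force
field is regularised by Gaussian fluid/elastic smoothing whose widths derive
from the requested control-point spacing, and the total displacement is
accumulated on the fixed grid.  It makes no claim of equivalence to any
production registration package; an external engine can be plugged in by
exchanging dense displacement fields through :class:`SpatialTransform`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.linalg import expm, logm

from .image_model import GridMismatchError, ImageGrid, ProbSegVolume, ScalarVolume, _INTERP_ORDER
from .similarity import EmptyFOVError, normalized_moments, cross_moment

__all__ = [
    "SpatialTransform",
    "RegistrationSpec",
    "Channel",
    "lncc_cost",
    "kld_cost",
    "register_multichannel",
    "apply_transform",
    "apply_transform_seg",
    "compose_transforms",
    "save_transform",
    "load_transform",
]

KLD_EPS = 1e-6
SIGMA_GUARD = 1e-9


@dataclass
class SpatialTransform:
    """Global affine plus dense displacement, in pull-back convention.

    A target (fixed-grid) voxel at physical position ``p`` reads the moving
    image at ``T(p) = A @ p + u(p)`` — global stage first, then the non-rigid
    displacement (mm) sampled on ``grid``.
    """

    grid: ImageGrid
    affine: np.ndarray = None  # 4x4 homogeneous, mm
    displacement: np.ndarray = None  # (3, x, y, z) mm, on `grid`

    def __post_init__(self) -> None:
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.displacement is None:
            self.displacement = np.zeros((3,) + self.grid.shape, dtype=np.float32)
        self.displacement = np.asarray(self.displacement, dtype=np.float32)
        if self.displacement.shape != (3,) + self.grid.shape:
            raise ValueError("displacement must be (3,) + grid.shape")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("non-finite displacement")

    @classmethod
    def identity(cls, grid: ImageGrid) -> "SpatialTransform":
        return cls(grid)

    def is_identity_affine(self, atol: float = 1e-12) -> bool:
        return np.allclose(self.affine, np.eye(4), atol=atol)

    def map_points(self, pts_mm: np.ndarray) -> np.ndarray:
        """Map physical points through the full transform.

        The displacement is sampled with linear interpolation at the points'
        positions on the transform grid.
        """
        pts_mm = np.asarray(pts_mm, dtype=float)
        mapped = pts_mm @ self.affine[:3, :3].T + self.affine[:3, 3]
        vox = self.grid.world_to_voxel(pts_mm)
        coords = vox.T  # (3, n)
        for ax in range(3):
            mapped[:, ax] += ndimage.map_coordinates(
                self.displacement[ax].astype(float), coords, order=1, mode="nearest"
            )
        return mapped

    def mapped_grid_points(self) -> np.ndarray:
        """Physical positions every fixed-grid voxel maps to, shape (3,)+shape."""
        idx = np.indices(self.grid.shape, dtype=float)
        pts = np.stack([idx[0], idx[1], idx[2]], axis=0)
        lin = self.grid.direction_matrix @ np.diag(self.grid.spacing)
        world = np.einsum("ij,j...->i...", lin, pts) + np.asarray(self.grid.origin).reshape(3, 1, 1, 1)
        mapped = np.einsum("ij,j...->i...", self.affine[:3, :3], world) + self.affine[:3, 3].reshape(3, 1, 1, 1)
        return mapped + self.displacement.astype(float)

    def jacobian_positive_fraction(self) -> float:
        """Fraction of voxels with positive Jacobian determinant (fold check)."""
        mapped = self.mapped_grid_points()
        grads = [np.gradient(mapped[i], *self.grid.spacing) for i in range(3)]
        jac = np.stack([np.stack(g, axis=0) for g in grads], axis=0)  # (i, d/dx_j, ...)
        det = (
            jac[0, 0] * (jac[1, 1] * jac[2, 2] - jac[1, 2] * jac[2, 1])
            - jac[0, 1] * (jac[1, 0] * jac[2, 2] - jac[1, 2] * jac[2, 0])
            + jac[0, 2] * (jac[1, 0] * jac[2, 1] - jac[1, 1] * jac[2, 0])
        )
        return float(np.mean(det > 0))


def save_transform(T: SpatialTransform, prefix) -> None:
    """Write a transform as ``<prefix>_affine.txt`` (4x4, mm) and, when the
    non-rigid part is non-zero, ``<prefix>_disp.nii.gz`` (3-vector mm field,
    pull-back convention noted in the NIfTI description)."""
    import nibabel as nib
    from pathlib import Path

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}_affine.txt", T.affine)
    if T.displacement.any():
        data = np.moveaxis(T.displacement, 0, -1).astype(np.float32)
        img = nib.Nifti1Image(data, T.grid.affine)
        img.header["descrip"] = b"pull-back displacement, mm"
        nib.save(img, f"{prefix}_disp.nii.gz")


def load_transform(prefix, grid: ImageGrid | None = None) -> SpatialTransform:
    """Inverse of :func:`save_transform`; a purely global transform (no
    displacement file on disk) needs ``grid`` to anchor the identity field."""
    import nibabel as nib
    from pathlib import Path

    prefix = Path(prefix)
    affine = np.loadtxt(f"{prefix}_affine.txt")
    disp_path = Path(f"{prefix}_disp.nii.gz")
    if disp_path.exists():
        img = nib.load(str(disp_path))
        from .image_model import _grid_from_affine

        fgrid = _grid_from_affine(img.shape[:3], img.affine)
        disp = np.moveaxis(np.asanyarray(img.dataobj), -1, 0)
        return SpatialTransform(fgrid, affine, disp.astype(np.float32))
    if grid is None:
        raise FileNotFoundError(f"{disp_path} missing and no grid given for a global-only transform")
    return SpatialTransform(grid, affine)


def compose_transforms(outer: SpatialTransform, inner: SpatialTransform, grid: ImageGrid) -> SpatialTransform:
    """Dense composition ``T(x) = outer(inner(x))`` sampled on ``grid``.

    The result carries an identity affine and a pure displacement field; the
    global stages of both inputs are folded into the field.
    """
    idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T
    world = grid.voxel_to_world(idx)
    mapped = outer.map_points(inner.map_points(world))
    disp = (mapped - world).T.reshape((3,) + grid.shape)
    return SpatialTransform(grid, np.eye(4), disp.astype(np.float32))


@dataclass
class Channel:
    """One fixed/moving image pair entering the multichannel cost."""

    fixed: ScalarVolume | ProbSegVolume
    moving: ScalarVolume | ProbSegVolume
    similarity: str = "LNCC"  # or "KLD"
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.similarity not in ("LNCC", "KLD"):
            raise ValueError(f"unknown channel similarity {self.similarity!r}")
        if self.similarity == "KLD" and not isinstance(self.fixed, ProbSegVolume):
            raise TypeError("KLD channels take probabilistic segmentations")


@dataclass
class RegistrationSpec:
    """Settings of the multichannel registration.

    ``control_spacing_mm`` plays the role the finest B-spline lattice spacing
    plays in lattice-parametrised registration: it sets the spatial scale of
    the deformation through the widths of the fluid/elastic Gaussian
    regularisers (fluid = spacing/2, elastic = spacing/4, scaled by
    ``regularization_weight``).
    """

    levels: int = 3
    control_spacing_mm: float = 10.0
    lncc_sigma_vox: float = 3.0
    iterations: tuple[int, ...] = (60, 30, 15)
    step_mm: float | None = None  # default: 0.4 * finest voxel spacing per level
    regularization_weight: float = 1.0
    convergence_tol: float = 1e-4
    patience: int = 8
    affine_mode: str = "affine"  # 'affine' | 'rigid' | 'translation' | 'none'
    symmetric_affine: bool = True
    interpolation: str = "linear"  # used during optimisation

    def __post_init__(self) -> None:
        if self.levels < 1 or self.control_spacing_mm <= 0:
            raise ValueError("levels >= 1 and positive control spacing required")
        if len(self.iterations) < self.levels:
            self.iterations = tuple(self.iterations) + (self.iterations[-1],) * (self.levels - len(self.iterations))


@dataclass
class RegistrationResult:
    transform: SpatialTransform
    cost_history: list[float]
    converged: bool
    diverged: bool


# ---------------------------------------------------------------------------
# Channel costs


def lncc_cost(
    F: ScalarVolume, M: ScalarVolume, sigma: float = 3.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Local normalised cross-correlation; cost is ``1 - mean LNCC``.

    Returns ``(cost, per_voxel_lncc, valid_mask)``.  Voxels where either local
    standard deviation vanishes are excluded from the mean (no structure to
    correlate).
    """
    if not F.grid.same_grid(M.grid):
        raise GridMismatchError("lncc_cost requires a shared grid")
    omega = F.fov & M.fov
    if not omega.any():
        raise EmptyFOVError("empty joint FOV")
    mf = normalized_moments(F, sigma, fov=omega)
    mm_ = normalized_moments(M, sigma, fov=omega)
    cov = cross_moment(F, M, mf, mm_, sigma, omega)
    denom = np.sqrt(np.maximum(mf.variance, 0.0) * np.maximum(mm_.variance, 0.0))
    valid = omega & mf.valid & mm_.valid & (np.sqrt(np.maximum(mf.variance, 0)) > SIGMA_GUARD) & (
        np.sqrt(np.maximum(mm_.variance, 0)) > SIGMA_GUARD
    )
    lncc = np.zeros(F.grid.shape)
    lncc[valid] = cov[valid] / denom[valid]
    lncc = np.clip(lncc, -1.0, 1.0)
    cost = 1.0 - float(lncc[valid].mean()) if valid.any() else 1.0
    return cost, lncc, valid


def kld_cost(F: ProbSegVolume, M: ProbSegVolume) -> tuple[float, np.ndarray]:
    """Mean per-voxel KL divergence between label posteriors, clamp at 1e-6.

    Returns ``(cost, per_voxel_kld)``; zero iff the (clamped) distributions
    agree everywhere.
    """
    if not F.grid.same_grid(M.grid):
        raise GridMismatchError("kld_cost requires a shared grid")
    if F.n_labels != M.n_labels:
        raise ValueError("label-count mismatch")

    def clamp(p: np.ndarray) -> np.ndarray:
        q = np.clip(p.astype(np.float64), KLD_EPS, 1.0)
        return q / q.sum(axis=-1, keepdims=True)

    p = clamp(F.probabilities)
    q = clamp(M.probabilities)
    per_voxel = np.sum(p * (np.log(p) - np.log(q)), axis=-1)
    return float(per_voxel.mean()), per_voxel


# ---------------------------------------------------------------------------
# Resampling


def apply_transform(vol: ScalarVolume, T: SpatialTransform, interpolation: str = "linear") -> ScalarVolume:
    """Pull-back resampling of a scalar volume onto the transform's grid.

    Reads beyond the moving FOV (or outside the moving grid) produce FOV = 0
    in the output; the output never invents data the moving image lacked.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = _INTERP_ORDER[interpolation]
    # exact identity on the same grid: copy through (any interpolation is the
    # identity at the sample points)
    if T.is_identity_affine() and not T.displacement.any() and T.grid.same_grid(vol.grid):
        return vol.copy()
    mapped = T.mapped_grid_points()  # (3,)+shape, mm
    pts = mapped.reshape(3, -1).T
    vox = vol.grid.world_to_voxel(pts).T.reshape((3,) + T.grid.shape)
    vals = ndimage.map_coordinates(vol.values.astype(np.float64), vox, order=order, mode="constant", cval=0.0)
    fov = ndimage.map_coordinates(vol.fov.astype(np.uint8), vox, order=0, mode="constant", cval=0) > 0
    inb = np.ones(T.grid.shape, dtype=bool)
    for ax in range(3):
        inb &= (vox[ax] > -0.5) & (vox[ax] < vol.grid.shape[ax] - 0.5)
    fov &= inb
    vals = np.where(fov, vals, 0.0)
    return ScalarVolume(T.grid, vals.astype(np.float32), fov, vol.modality)


def apply_transform_seg(seg: ProbSegVolume, T: SpatialTransform, interpolation: str = "nearest") -> ProbSegVolume:
    """Propagate a probabilistic segmentation; nearest keeps one-hot exact.

    With linear interpolation the channels are interpolated and renormalised;
    out-of-support voxels become pure background.
    """
    mapped = T.mapped_grid_points()
    pts = mapped.reshape(3, -1).T
    vox = seg.grid.world_to_voxel(pts).T.reshape((3,) + T.grid.shape)
    inb = np.ones(T.grid.shape, dtype=bool)
    for ax in range(3):
        inb &= (vox[ax] > -0.5) & (vox[ax] < seg.grid.shape[ax] - 0.5)
    if interpolation == "nearest":
        labels = ndimage.map_coordinates(seg.argmax_labels(), vox, order=0, mode="constant", cval=0)
        labels[~inb] = 0
        return ProbSegVolume.from_labels(T.grid, labels, seg.n_labels)
    order = _INTERP_ORDER[interpolation]
    out = np.zeros(T.grid.shape + (seg.n_labels,), dtype=np.float64)
    for l in range(seg.n_labels):
        out[..., l] = ndimage.map_coordinates(seg.probabilities[..., l].astype(np.float64), vox, order=order, mode="constant", cval=0.0)
    out[~inb] = 0.0
    out[~inb, 0] = 1.0
    out = np.clip(out, 0.0, None)
    tot = out.sum(axis=-1, keepdims=True)
    bad = tot[..., 0] <= 1e-8
    out[bad] = 0.0
    out[bad, 0] = 1.0
    tot = out.sum(axis=-1, keepdims=True)
    return ProbSegVolume(T.grid, (out / tot).astype(np.float32))


# ---------------------------------------------------------------------------
# Internal helpers for the reference optimiser


def _downsample_scalar(vol: ScalarVolume, factor: int) -> ScalarVolume:
    if factor == 1:
        return vol
    g = vol.grid
    new_shape = tuple(max(1, int(np.ceil(s / factor))) for s in g.shape)
    new_spacing = tuple(sp * factor for sp in g.spacing)
    # voxel-centre alignment: new voxel i sits at input voxel i*factor + (factor-1)/2
    off = (factor - 1) / 2.0
    coords = np.indices(new_shape, dtype=float) * factor + off
    sm = ndimage.gaussian_filter(vol.values.astype(np.float64), sigma=0.5 * factor, mode="nearest")
    vals = ndimage.map_coordinates(sm, coords, order=1, mode="nearest")
    fov = ndimage.map_coordinates(vol.fov.astype(np.uint8), coords, order=0, mode="constant", cval=0) > 0
    origin = np.asarray(g.origin) + g.direction_matrix @ (np.asarray(g.spacing) * off)
    grid = ImageGrid(new_shape, new_spacing, tuple(origin), g.direction)
    return ScalarVolume(grid, vals.astype(np.float32), fov, vol.modality)


def _downsample_seg(seg: ProbSegVolume, factor: int) -> ProbSegVolume:
    if factor == 1:
        return seg
    g = seg.grid
    new_shape = tuple(max(1, int(np.ceil(s / factor))) for s in g.shape)
    new_spacing = tuple(sp * factor for sp in g.spacing)
    off = (factor - 1) / 2.0
    coords = np.indices(new_shape, dtype=float) * factor + off
    out = np.zeros(new_shape + (seg.n_labels,), dtype=np.float64)
    for l in range(seg.n_labels):
        sm = ndimage.gaussian_filter(seg.probabilities[..., l].astype(np.float64), sigma=0.5 * factor, mode="nearest")
        out[..., l] = ndimage.map_coordinates(sm, coords, order=1, mode="nearest")
    out = np.clip(out, 0, None)
    out /= out.sum(axis=-1, keepdims=True)
    origin = np.asarray(g.origin) + g.direction_matrix @ (np.asarray(g.spacing) * off)
    grid = ImageGrid(new_shape, new_spacing, tuple(origin), g.direction)
    return ProbSegVolume(grid, out.astype(np.float32))


def _standardize(vol: ScalarVolume, sigma_vox: float) -> tuple[np.ndarray, np.ndarray]:
    """Locally standardised image (zero local mean, unit local std) + mask."""
    m = normalized_moments(vol, sigma_vox)
    std = np.sqrt(np.maximum(m.variance, 0.0))
    inside = vol.fov & m.valid
    floor = 0.05 * (std[inside].mean() if inside.any() else 1.0) + 1e-12
    z = np.where(inside, (vol.values - m.mean) / np.maximum(std, floor), 0.0)
    return z.astype(np.float64), inside


def _modality_group(vol) -> str:
    m = getattr(vol, "modality", "T2")
    return "CT" if m in ("CT", "pCT") else m


@dataclass
class _LevelChannel:
    kind: str
    weight: float
    fixed_arrays: list[np.ndarray]  # standardised intensity or per-label probs
    fixed_mask: np.ndarray
    moving_arrays: list[np.ndarray]
    moving_mask: np.ndarray
    moving_grid: ImageGrid
    fixed_vol: ScalarVolume | ProbSegVolume
    moving_vol: ScalarVolume | ProbSegVolume
    multimodal: bool = False


def _prepare_level_channel(ch: Channel, factor: int, lncc_sigma: float) -> _LevelChannel:
    if ch.similarity == "LNCC":
        f = _downsample_scalar(ch.fixed, factor)
        m = _downsample_scalar(ch.moving, factor)
        fz, fmask = _standardize(f, lncc_sigma)
        mz, mmask = _standardize(m, lncc_sigma)
        # channels pairing different contrasts (T2 vs CT, T1 vs T2) may be
        # locally anti-correlated; the force must follow |LNCC|, not SSD
        cross = _modality_group(ch.fixed) != _modality_group(ch.moving)
        return _LevelChannel("LNCC", ch.weight, [fz], fmask, [mz], mmask, m.grid, f, m, multimodal=cross)
    f = _downsample_seg(ch.fixed, factor)
    m = _downsample_seg(ch.moving, factor)
    # drop the background channel from the force (organ channels carry the
    # structure, background is their complement) and soften the hard label
    # edges: raw one-hot probability steps alias badly under interpolation
    # and produce unstable single-voxel forces
    smooth = lambda a: ndimage.gaussian_filter(a, sigma=1.0, mode="nearest")
    fArr = [smooth(f.probabilities[..., l].astype(np.float64)) for l in range(1, f.n_labels)]
    mArr = [smooth(m.probabilities[..., l].astype(np.float64)) for l in range(1, m.n_labels)]
    ones = np.ones(f.grid.shape, dtype=bool)
    return _LevelChannel("KLD", ch.weight, fArr, ones, mArr, ones, m.grid, f, m)


def _sample(arr: np.ndarray, vox: np.ndarray, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(arr, vox, order=order, mode="constant", cval=0.0)


def _affine_from_params(p: np.ndarray, mode: str, center: np.ndarray) -> np.ndarray:
    t = p[:3]
    A = np.eye(4)
    R = np.eye(3)
    S = np.eye(3)
    if mode in ("rigid", "affine"):
        rx, ry, rz = p[3:6]
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        R = (
            np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
            @ np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
            @ np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        )
    if mode == "affine":
        S = np.diag(np.exp(p[6:9]))
    lin = R @ S
    A[:3, :3] = lin
    A[:3, 3] = t + center - lin @ center
    return A


def _n_affine_params(mode: str) -> int:
    return {"translation": 3, "rigid": 6, "affine": 9}[mode]


def _nmi_cost(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """``2 - NMI``: 0 for perfectly predictable pairs, ~1 for independence."""
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    s = hist.sum()
    if s == 0:
        return 1.0
    p = hist / s
    px, py = p.sum(axis=1), p.sum(axis=0)
    if np.count_nonzero(px) < 2 or np.count_nonzero(py) < 2:
        return 1.0

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    return 2.0 - (ent(px) + ent(py)) / ent(p.ravel())


def _affine_cost(channels: list[_LevelChannel], A: np.ndarray, fixed_grid: ImageGrid, world: np.ndarray) -> float:
    """Global-stage objective: NMI for intensity channels (modality-agnostic,
    no local-correlation degeneracies), mass-normalised label SSD for
    segmentation channels; every term is O(1)."""
    mapped = world @ A[:3, :3].T + A[:3, 3]
    total = 0.0
    for ch in channels:
        vox = ch.moving_grid.world_to_voxel(mapped).T.reshape((3,) + fixed_grid.shape)
        if ch.kind == "LNCC":
            mvol = ch.moving_vol
            mw = _sample(np.asarray(mvol.values, dtype=np.float64), vox)
            mask = _sample(mvol.fov.astype(np.float64), vox, order=0) > 0.5
            inb = np.ones(fixed_grid.shape, dtype=bool)
            for ax in range(3):
                inb &= (vox[ax] > -0.5) & (vox[ax] < mvol.grid.shape[ax] - 0.5)
            mask &= inb & ch.fixed_vol.fov
            if mask.sum() < 64:
                total += 2.0 * ch.weight
                continue
            total += ch.weight * _nmi_cost(np.asarray(ch.fixed_vol.values, dtype=np.float64)[mask], mw[mask])
        else:
            sse = np.zeros(fixed_grid.shape)
            mass = np.zeros(fixed_grid.shape)
            for fa, ma in zip(ch.fixed_arrays, ch.moving_arrays):
                mw = _sample(ma, vox)
                sse += (fa - mw) ** 2
                mass += 0.5 * (fa**2 + mw**2)
            denom = float(mass.sum())
            total += ch.weight * (float(sse.sum()) / denom if denom > 0 else 2.0)
    return total


def _optimize_affine(
    channels: list[_LevelChannel], fixed_grid: ImageGrid, mode: str, center: np.ndarray, x0: np.ndarray | None = None
) -> np.ndarray:
    from scipy.optimize import minimize

    idx = np.indices(fixed_grid.shape, dtype=float).reshape(3, -1).T
    world = fixed_grid.voxel_to_world(idx)
    n = _n_affine_params(mode)

    def f(p):
        return _affine_cost(channels, _affine_from_params(p, mode, center), fixed_grid, world)

    res = minimize(
        f,
        np.zeros(n) if x0 is None else np.asarray(x0, dtype=float),
        method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000},
    )
    return res.x


def _affine_stage(
    channels: list[Channel], factors: list[int], lncc_sig: float, mode: str, swap: bool = False
) -> np.ndarray:
    """Coarse-to-fine Powell affine estimation over the two coarsest levels."""
    x = None
    for factor in sorted(set(factors[: 2 if len(factors) > 1 else 1]), reverse=True):
        lchs = [_prepare_level_channel(ch, factor, lncc_sig) for ch in channels]
        if swap:
            lchs = [
                _LevelChannel(c.kind, c.weight, c.moving_arrays, c.moving_mask, c.fixed_arrays, c.fixed_mask,
                              c.fixed_vol.grid, c.moving_vol, c.fixed_vol)
                for c in lchs
            ]
        grid = lchs[0].fixed_vol.grid
        center = np.asarray(grid.voxel_to_world(np.array([(s - 1) / 2.0 for s in grid.shape])))
        x = _optimize_affine(lchs, grid, mode, center, x)
    return _affine_from_params(x, mode, center)


def _log_affine_average(A_fm: np.ndarray, A_mf: np.ndarray) -> np.ndarray:
    """Symmetrise the two directions in the log-affine sense."""
    try:
        la = np.real(logm(A_fm))
        lb = np.real(logm(np.linalg.inv(A_mf)))
        return np.real(expm(0.5 * (la + lb)))
    except Exception:  # non-diagonalisable corner case: keep forward result
        return A_fm


def register_multichannel(
    channels: list[Channel],
    spec: RegistrationSpec | None = None,
    init: SpatialTransform | None = None,
) -> RegistrationResult:
    """Estimate the transform mapping the fixed space onto the moving space.

    Global stage: the affine minimising the summed channel costs, estimated in
    both directions and averaged in the log-affine sense (symmetric).
    Non-rigid stage: coarse-to-fine dense displacement updates from
    sum-of-squares forces on locally standardised intensity channels (an LNCC
    ascent direction) and on label-probability channels, with Gaussian
    fluid/elastic regularisation.  Fully deterministic.

    A run whose internal cost rises beyond the patience window is flagged
    ``diverged`` and returns the best transform seen.

    ``init`` warm-starts the optimisation: its affine replaces the global
    stage and its displacement seeds the coarsest pyramid level.
    """
    if spec is None:
        spec = RegistrationSpec()
    if not channels:
        raise ValueError("at least one channel required")
    fixed_grid = channels[0].fixed.grid
    for ch in channels:
        if not ch.fixed.grid.same_grid(fixed_grid):
            raise GridMismatchError("all fixed channels must share one grid")

    factors = [2 ** (spec.levels - 1 - l) for l in range(spec.levels)]
    lncc_sig = spec.lncc_sigma_vox

    # ---- global stage (coarse-to-fine over the two coarsest levels)
    if init is not None:
        A = np.asarray(init.affine, dtype=float)
    elif spec.affine_mode != "none":
        A_fm = _affine_stage(channels, factors, lncc_sig, spec.affine_mode)
        if spec.symmetric_affine:
            A_mf = _affine_stage(channels, factors, lncc_sig, spec.affine_mode, swap=True)
            A = _log_affine_average(A_fm, A_mf)
        else:
            A = A_fm
    else:
        A = np.eye(4)

    # ---- non-rigid stage
    disp = None  # (3,)+level shape, mm
    cost_history: list[float] = []
    diverged = False
    prev_grid = None
    for li, factor in enumerate(factors):
        lchs = [_prepare_level_channel(ch, factor, lncc_sig) for ch in channels]
        lgrid = lchs[0].fixed_vol.grid
        spacing = np.asarray(lgrid.spacing)
        if disp is None:
            disp = np.zeros((3,) + lgrid.shape)
            if init is not None and init.displacement.any():
                idxc = np.indices(lgrid.shape, dtype=float).reshape(3, -1).T
                worldc = lgrid.voxel_to_world(idxc)
                voxp = init.grid.world_to_voxel(worldc).T.reshape((3,) + lgrid.shape)
                for ax in range(3):
                    disp[ax] = ndimage.map_coordinates(
                        init.displacement[ax].astype(float), voxp, order=1, mode="nearest"
                    )
        else:
            up = np.zeros((3,) + lgrid.shape)
            idxc = np.indices(lgrid.shape, dtype=float).reshape(3, -1).T
            worldc = lgrid.voxel_to_world(idxc)
            voxp = prev_grid.world_to_voxel(worldc).T.reshape((3,) + lgrid.shape)
            for ax in range(3):
                up[ax] = ndimage.map_coordinates(disp[ax], voxp, order=1, mode="nearest")
            disp = up
        prev_grid = lgrid

        idx = np.indices(lgrid.shape, dtype=float).reshape(3, -1).T
        world = lgrid.voxel_to_world(idx)
        world_aff = (world @ A[:3, :3].T + A[:3, 3]).T.reshape((3,) + lgrid.shape)

        fluid_mm = max(spec.control_spacing_mm / 2.0, 0.8 * float(spacing.min())) * spec.regularization_weight
        elastic_mm = max(spec.control_spacing_mm / 4.0, 0.5 * float(spacing.min())) * spec.regularization_weight
        # step is tied to the full-resolution voxel size: coarse levels iterate
        # often and cheaply rather than taking oscillation-prone giant steps
        step = spec.step_mm if spec.step_mm is not None else 0.45 * float(min(fixed_grid.spacing))

        best_cost = np.inf
        best_disp = disp.copy()
        first_cost = None
        stall = 0
        for it in range(spec.iterations[li]):
            mapped = world_aff + disp
            force = np.zeros_like(disp)
            cost = 0.0
            for ch in lchs:
                pts = mapped.reshape(3, -1).T
                vox = ch.moving_grid.world_to_voxel(pts).T.reshape((3,) + lgrid.shape)
                cforce = np.zeros_like(disp)
                if ch.kind == "LNCC":
                    mw = _sample(ch.moving_arrays[0], vox)
                    mask = (_sample(ch.moving_mask.astype(np.float64), vox, order=0) > 0.5) & ch.fixed_mask
                    fz = ch.fixed_arrays[0]
                    if ch.multimodal:
                        # sign-adaptive |LNCC| ascent: align M to F where they
                        # correlate positively, to -F where negatively, and
                        # stay silent where the local correlation is weak
                        prod = np.where(mask, fz * mw, 0.0)
                        corr = np.clip(ndimage.gaussian_filter(prod, sigma=lncc_sig, mode="nearest"), -1.5, 1.5)
                        rho = np.where(np.abs(corr) > 0.1, np.sign(corr), 0.0)
                        r = np.where(mask, rho * fz - mw, 0.0) * (rho != 0)
                        cost += ch.weight * (1.0 - float(np.abs(corr[mask]).clip(0, 1).mean())) if mask.any() else 2.0 * ch.weight
                    else:
                        r = np.where(mask, fz - mw, 0.0)
                        cost += ch.weight * float(np.mean(r[mask] ** 2)) if mask.any() else 2.0 * ch.weight
                    g = np.gradient(mw, *spacing)
                    for ax in range(3):
                        cforce[ax] = r * g[ax]
                else:
                    for fa, ma in zip(ch.fixed_arrays, ch.moving_arrays):
                        mw = _sample(ma, vox)
                        r = fa - mw
                        g = np.gradient(mw, *spacing)
                        for ax in range(3):
                            cforce[ax] += r * g[ax]
                        cost += ch.weight * float(np.mean(r**2))
                # equalise channel force scales: a channel with sharp residual
                # edges (label maps) must not drown out the others
                scale = np.percentile(np.abs(cforce), 99.5)
                if scale > 1e-14:
                    force += (ch.weight / scale) * cforce
            cost_history.append(cost)
            if first_cost is None:
                first_cost = cost
            if not np.isfinite(best_cost) or cost < best_cost - spec.convergence_tol * max(abs(best_cost), 1e-12):
                best_cost = cost
                best_disp = disp.copy()
                stall = 0
            else:
                stall += 1
                if stall > spec.patience:
                    break
            for ax in range(3):
                force[ax] = ndimage.gaussian_filter(force[ax], sigma=fluid_mm / spacing, mode="nearest")
            fmax = float(np.abs(force).max())
            if fmax < 1e-14:
                break
            disp = disp + force * (step / fmax)
            for ax in range(3):
                disp[ax] = ndimage.gaussian_filter(disp[ax], sigma=elastic_mm / spacing, mode="nearest")
        # a level that never improved on its starting cost signals divergence
        if first_cost is not None and best_cost > first_cost * (1 + 0.05):
            diverged = True
        disp = best_disp

    # resample displacement to the full-resolution fixed grid
    if prev_grid is not None and not prev_grid.same_grid(fixed_grid):
        idxf = np.indices(fixed_grid.shape, dtype=float).reshape(3, -1).T
        worldf = fixed_grid.voxel_to_world(idxf)
        voxp = prev_grid.world_to_voxel(worldf).T.reshape((3,) + fixed_grid.shape)
        full = np.zeros((3,) + fixed_grid.shape)
        for ax in range(3):
            full[ax] = ndimage.map_coordinates(disp[ax], voxp, order=1, mode="nearest")
        disp = full
    T = SpatialTransform(fixed_grid, A, disp.astype(np.float32))
    return RegistrationResult(T, cost_history, converged=not diverged, diverged=diverged)
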