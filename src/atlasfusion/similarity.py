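"""Convolution-based local similarity measures over irregular fields of view.

Local image statistics are computed by density-normalised convolution: a
Gaussian kernel is convolved with the masked image and with the mask itself,
and the ratio recovers unbiased local moments wherever any data falls under
the kernel.  This makes the structural-similarity score (ROI-SSIM) and the
local fuzzy Dice (LDSC) well defined on images whose fields of view only
partially overlap — e.g. an MR cropped tighter than the CT of the same
subject.  Voxels outside the joint FOV carry a ``-inf`` sentinel plus an
explicit validity mask so downstream ranking can exclude them without NaN
arithmetic.

The combined local similarity (LSIM) that drives atlas ranking sums the
ROI-SSIM of the T2 and T1 channels and, from the second pipeline iteration
on, the ROI-SSIM between the previous pseudo-CT and the propagated atlas CT
and the LDSC between the previous probabilistic segmentation and the
propagated atlas labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_model import GridMismatchError, ImageGrid, ProbSegVolume, ScalarVolume

__all__ = [
    "LocalMoments",
    "SimilarityVolume",
    "gaussian_smooth",
    "normalized_moments",
    "cross_moment",
    "roi_ssim",
    "local_fuzzy_dice",
    "lsim",
    "ssim_constants",
]

#: Kernel width in voxels; the kernel is truncated at 3 sigma.
DEFAULT_SIGMA_G = 3.0
TRUNCATE = 3.0
DENSITY_EPS = 1e-12
VAR_CLAMP = 1e-9


class EmptyFOVError(ValueError):
    """Raised when a similarity is requested over an empty field of view."""


@dataclass
class SimilarityVolume:
    """Per-voxel similarity score with ``-inf`` sentinel outside validity."""

    grid: ImageGrid
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.values[~self.valid] = -np.inf

    def __add__(self, other: "SimilarityVolume") -> "SimilarityVolume":
        valid = self.valid & other.valid
        vals = np.where(valid, self.values + other.values, -np.inf)
        return SimilarityVolume(self.grid, vals, valid)

    def scaled(self, w: float) -> "SimilarityVolume":
        return SimilarityVolume(self.grid, np.where(self.valid, self.values * w, -np.inf), self.valid)

    def save(self, path) -> None:
        """Write scores as NIfTI with the validity mask as a sidecar; the
        sentinel is replaced by 0 in the file (the mask is authoritative)."""
        from .image_model import ScalarVolume, write_volume

        vals = np.where(self.valid, self.values, 0.0).astype(np.float32)
        write_volume(ScalarVolume(self.grid, vals, self.valid, "T2"), path)


@dataclass
class LocalMoments:
    """Density-normalised local mean / second moment / variance of an image."""

    grid: ImageGrid
    mean: np.ndarray
    second_moment: np.ndarray
    variance: np.ndarray
    density: np.ndarray  # G * Omega
    valid: np.ndarray
    sigma_g: float


def gaussian_smooth(arr: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian convolution, zero-padded, truncated at 3 sigma."""
    return ndimage.gaussian_filter(np.asarray(arr, dtype=np.float64), sigma=sigma, mode="constant", cval=0.0, truncate=TRUNCATE)


def normalized_moments(vol: ScalarVolume, sigma_g: float = DEFAULT_SIGMA_G, fov: np.ndarray | None = None) -> LocalMoments:
    """Local mean and variance via density-normalised convolution.

    ``mu(x) = [G * (I . Omega)](x) / [G * Omega](x)`` with the variance from
    the normalised second moment.  Where the smoothed density falls below
    1e-12 the moments are undefined and the voxel is marked outside the FOV.
    """
    if not sigma_g > 0:
        raise ValueError("sigma_g must be positive")
    omega = vol.fov if fov is None else np.asarray(fov, dtype=bool)
    if not omega.any():
        raise EmptyFOVError("empty FOV")
    om = omega.astype(np.float64)
    vals = np.where(omega, vol.values, 0.0).astype(np.float64)
    density = gaussian_smooth(om, sigma_g)
    valid = density > DENSITY_EPS
    safe = np.where(valid, density, 1.0)
    mean = gaussian_smooth(vals, sigma_g) / safe
    second = gaussian_smooth(vals * vals, sigma_g) / safe
    var = second - mean * mean
    var[var < VAR_CLAMP] = np.maximum(var[var < VAR_CLAMP], 0.0)  # clamp tiny negatives from cancellation
    mean[~valid] = 0.0
    second[~valid] = 0.0
    var[~valid] = 0.0
    return LocalMoments(vol.grid, mean, second, var, density, valid, sigma_g)


def cross_moment(
    I: ScalarVolume, J: ScalarVolume, mi: LocalMoments, mj: LocalMoments, sigma_g: float, omega: np.ndarray
) -> np.ndarray:
    """Local covariance sigma_IJ = mu_{I.J} - mu_I mu_J over the joint FOV."""
    prod = np.where(omega, I.values.astype(np.float64) * J.values.astype(np.float64), 0.0)
    safe = np.where(mi.valid, mi.density, 1.0)
    mu_ij = gaussian_smooth(prod, sigma_g) / safe
    return mu_ij - mi.mean * mj.mean


def ssim_constants(vol: ScalarVolume, k1: float = 0.01, k2: float = 0.03) -> tuple[float, float]:
    """Standard SSIM stabilisers ``C = (k . D)^2`` from the dynamic range D.

    CT-like modalities use a fixed 2000 HU range; MR uses the robust
    1st-99th percentile range inside the FOV.
    """
    if vol.modality in ("CT", "pCT"):
        d = 2000.0
    else:
        inside = vol.values[vol.fov]
        lo, hi = np.percentile(inside, [1, 99])
        d = float(max(hi - lo, 1e-6))
    return (k1 * d) ** 2, (k2 * d) ** 2


def roi_ssim(
    I: ScalarVolume,
    J: ScalarVolume,
    sigma_g: float = DEFAULT_SIGMA_G,
    C1: float | None = None,
    C2: float | None = None,
) -> SimilarityVolume:
    """Structural similarity over the joint FOV via normalised convolution.

    Product of the luminance term ``(2 mu_I mu_J + C1)/(mu_I^2 + mu_J^2 + C1)``
    and the structure term ``(2 sigma_IJ + C2)/(sigma_I^2 + sigma_J^2 + C2)``;
    scores are in [-1, 1] inside the joint FOV and ``-inf`` outside.
    """
    if not I.grid.same_grid(J.grid):
        raise GridMismatchError("roi_ssim requires a shared grid")
    if C1 is None or C2 is None:
        c1a, c2a = ssim_constants(I)
        c1b, c2b = ssim_constants(J)
        C1 = C1 if C1 is not None else float(np.sqrt(c1a * c1b))
        C2 = C2 if C2 is not None else float(np.sqrt(c2a * c2b))
    if C1 <= 0 or C2 <= 0:
        raise ValueError("SSIM constants must be positive")
    omega = I.fov & J.fov
    if not omega.any():
        raise EmptyFOVError("joint FOV is empty")
    mi = normalized_moments(I, sigma_g, fov=omega)
    mj = normalized_moments(J, sigma_g, fov=omega)
    cov = cross_moment(I, J, mi, mj, sigma_g, omega)
    lum = (2.0 * mi.mean * mj.mean + C1) / (mi.mean**2 + mj.mean**2 + C1)
    struct = (2.0 * cov + C2) / (mi.variance + mj.variance + C2)
    score = np.clip(lum * struct, -1.0, 1.0)
    valid = omega & mi.valid & mj.valid
    return SimilarityVolume(I.grid, np.where(valid, score, -np.inf), valid)


def local_fuzzy_dice(
    IS: ProbSegVolume,
    JS: ProbSegVolume,
    sigma_g: float = DEFAULT_SIGMA_G,
    include_background: bool = False,
) -> SimilarityVolume:
    """Local fuzzy Dice between probabilistic segmentations, summed over labels.

    Each label's probability map is Gaussian-smoothed and the per-voxel term
    is ``2 min(a, b) / (a + b)``; a label with zero smoothed mass in both
    images contributes 0 (absent organs should not inflate agreement).  The
    background label is excluded by default so that the organ terms are not
    swamped; the result then lies in [0, L-1] ([0, L] if included).
    """
    if not IS.grid.same_grid(JS.grid):
        raise GridMismatchError("local_fuzzy_dice requires a shared grid")
    if IS.n_labels != JS.n_labels:
        raise ValueError("label-count mismatch")
    start = 0 if include_background else 1
    score = np.zeros(IS.grid.shape, dtype=np.float64)
    for l in range(start, IS.n_labels):
        a = gaussian_smooth(IS.probabilities[..., l], sigma_g)
        b = gaussian_smooth(JS.probabilities[..., l], sigma_g)
        den = a + b
        num = 2.0 * np.minimum(a, b)
        score += np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return SimilarityVolume(IS.grid, score, np.ones(IS.grid.shape, dtype=bool))


def lsim(
    target_t2: ScalarVolume,
    target_t1: ScalarVolume,
    j_t2: ScalarVolume,
    j_t1: ScalarVolume,
    iteration: int,
    target_pct: ScalarVolume | None = None,
    target_seg: ProbSegVolume | None = None,
    j_ct: ScalarVolume | None = None,
    j_seg: ProbSegVolume | None = None,
    sigma_g: float = DEFAULT_SIGMA_G,
    channel_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    include_background: bool = False,
) -> SimilarityVolume:
    """Combined local similarity between the target state and one mapped atlas.

    At the first iteration only the two MR channels are compared (no previous
    pseudo-CT or segmentation exists); later iterations add the CT channel
    (previous pseudo-CT vs propagated atlas CT) and the segmentation channel
    (previous probabilistic labels vs propagated atlas labels, local fuzzy
    Dice).  Voxels invalid in any used channel are ``-inf``.
    """
    if iteration < 1:
        raise ValueError("iteration must be >= 1")
    wt2, wt1, wct, wseg = channel_weights
    total = roi_ssim(target_t2, j_t2, sigma_g).scaled(wt2) + roi_ssim(target_t1, j_t1, sigma_g).scaled(wt1)
    if iteration >= 2:
        if target_pct is None or target_seg is None or j_ct is None or j_seg is None:
            raise ValueError("iterations >= 2 need the previous pseudo-CT/segmentation and atlas CT/labels")
        if wct != 0:
            total = total + roi_ssim(target_pct, j_ct, sigma_g).scaled(wct)
        if wseg != 0:
            total = total + local_fuzzy_dice(target_seg, j_seg, sigma_g, include_background).scaled(wseg)
    return total
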