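"""Synthetic pelvic-like cohort generator with ground truth.

Clinical multi-modal pelvic datasets cannot ship with the package, so every
higher-level component is exercised on a digital phantom: a laterally
symmetric template of ellipsoidal organs (bladder, prostate, rectum modelled
as a bent tube, paired femur heads, a pelvic bone shell, a body outline)
rendered into CT (Hounsfield units), T1- and T2-weighted contrasts through
per-tissue intensity tables, with modality noise, a smooth multiplicative MR
bias field, and a deliberately tighter MR field of view than the CT one.

Cohort subjects are the template warped by independent random smooth
deformations drawn from the same family of coarse-lattice displacements the
registration module optimises (deliberately easy: failures then indicate
implementation bugs rather than model mismatch).  The true warps are
retained so registration accuracy can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_model import (
    AtlasDatabase,
    AtlasRecord,
    ImageGrid,
    LabelDictionary,
    ProbSegVolume,
    ScalarVolume,
)
from .registration import SpatialTransform, apply_transform, apply_transform_seg

__all__ = [
    "PhantomSpec",
    "TemplateResult",
    "CohortResult",
    "MisalignResult",
    "generate_template",
    "generate_cohort",
    "misalign_record",
    "random_smooth_displacement",
    "warp_record",
]

# label indices follow the default label dictionary
BG, PROSTATE, BLADDER, RECTUM, LFEM, RFEM, BODY = range(7)

#: per-tissue rendering tables: label -> (CT HU, T1, T2)
DEFAULT_INTENSITIES = {
    BG: (-1000.0, 0.0, 0.0),
    PROSTATE: (40.0, 90.0, 110.0),
    BLADDER: (10.0, 50.0, 200.0),
    RECTUM: (25.0, 70.0, 60.0),
    LFEM: (700.0, 140.0, 45.0),
    RFEM: (700.0, 140.0, 45.0),
    BODY: (30.0, 110.0, 80.0),
}
BONE_SHELL_INTENSITY = (1000.0, 60.0, 25.0)


@dataclass
class PhantomSpec:
    """Geometry, rendering and variability settings of the synthetic cohort.

    Defaults give a 64^3 volume at 3 mm isotropic spacing (a scaled-down
    pelvis), CT noise 15 HU, MR noise 4 (arbitrary units against tissue
    means of 40-200), a 15% multiplicative MR bias field and 5 mm-amplitude
    smooth inter-subject deformations.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sigma: dict = field(default_factory=lambda: {"CT": 15.0, "T1": 4.0, "T2": 4.0})
    bias_amplitude: float = 0.15
    deformation_mm: float = 5.0
    deformation_knots: int = 5
    mr_crop_vox: tuple[int, int] = (4, 6)  # columns (x) and slices (z) trimmed on each side
    seed: int = 0

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.shape, self.spacing)


@dataclass
class TemplateResult:
    record: AtlasRecord
    label_map: np.ndarray
    bone_mask: np.ndarray  # femur heads + pelvic shell
    body_mask: np.ndarray
    labels: LabelDictionary


@dataclass
class SubjectTruth:
    warp: SpatialTransform
    label_map: np.ndarray
    bone_mask: np.ndarray
    body_mask: np.ndarray


@dataclass
class CohortResult:
    db: AtlasDatabase
    target: AtlasRecord
    target_truth: SubjectTruth
    truths: dict  # atlas id -> SubjectTruth
    spec: PhantomSpec


@dataclass
class MisalignResult:
    record: AtlasRecord
    ct_seg: ProbSegVolume  # the CT-side manual segmentation, warped with the CT
    true_warp: SpatialTransform


def _centered_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel coordinates centred so that index i and S-1-i mirror exactly."""
    ax = [np.arange(s, dtype=float) - (s - 1) / 2.0 for s in shape]
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid(x, y, z, cx, cy, cz, rx, ry, rz) -> np.ndarray:
    return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 + ((z - cz) / rz) ** 2 <= 1.0


def _template_labels(spec: PhantomSpec, geometry_jitter: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Paint the label map; later organs overwrite soft tissue only.

    Returns (label_map, bone_shell_mask) — the shell is rendered as bone but
    is not an organ label of its own.
    """
    sx, sy, sz = spec.shape
    x, y, z = _centered_coords(spec.shape)
    j = geometry_jitter or {}
    w = sx / 2.0  # half extents in voxels
    labels = np.zeros(spec.shape, dtype=np.int32)

    # body: ellipse in (x, y), long in z
    body = _ellipsoid(x, y, z, 0, 0, 0, 0.84 * w, 0.70 * w, 1.6 * sz / 2.0)
    labels[body] = BODY

    # bladder (anterior), prostate (below/behind bladder), rectum (posterior tube);
    # painted first and in this priority so each organ keeps its analytic shape
    rb = j.get("bladder_r", 0.20 * w)
    bladder = _ellipsoid(x, y, z, 0, -0.28 * w, 0.10 * sz / 2.0, rb, 0.8 * rb, 1.1 * rb)
    prostate = _ellipsoid(x, y, z, 0, -0.05 * w, -0.12 * sz / 2.0, 0.11 * w, 0.10 * w, 0.09 * sz / 2.0)
    rr = j.get("rectum_r", 0.075 * w)
    bend = j.get("rectum_bend", 0.10 * w)
    yc = 0.22 * w + bend * np.sin(np.pi * z / sz)
    rectum = ((x / rr) ** 2 + ((y - yc) / rr) ** 2 <= 1.0) & (np.abs(z) < 0.7 * sz / 2.0)
    for organ, lab in ((bladder, BLADDER), (prostate, PROSTATE), (rectum, RECTUM)):
        labels[organ & (labels == BODY)] = lab

    # femur heads, laterally symmetric
    rfh = j.get("femur_r", 0.13 * w)
    fhl = _ellipsoid(x, y, z, +0.56 * w, 0.10 * w, 0, rfh, rfh, rfh)
    fhr = _ellipsoid(x, y, z, -0.56 * w, 0.10 * w, 0, rfh, rfh, rfh)
    labels[fhl & (labels == BODY)] = LFEM
    labels[fhr & (labels == BODY)] = RFEM

    # pelvic bone shell: ellipsoid shell in a central z band, yielding to organs
    band = np.abs(z) < 0.45 * sz / 2.0
    outer = _ellipsoid(x, y, z, 0, 0.05 * w, 0, 0.62 * w, 0.50 * w, 0.60 * sz / 2.0)
    inner = _ellipsoid(x, y, z, 0, 0.05 * w, 0, 0.50 * w, 0.38 * w, 0.55 * sz / 2.0)
    shell = outer & ~inner & band & (labels == BODY)
    return labels, shell


def _render(labels: np.ndarray, shell: np.ndarray, spec: PhantomSpec, modality: str) -> np.ndarray:
    col = {"CT": 0, "T1": 1, "T2": 2}[modality]
    lut = np.zeros(max(spec.intensities) + 1)
    for lab, vals in spec.intensities.items():
        lut[lab] = vals[col]
    out = lut[labels]
    out[shell] = BONE_SHELL_INTENSITY[col]
    return out.astype(np.float64)


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    coarse = rng.standard_normal((3, 3, 3))
    f = ndimage.zoom(coarse, [s / 3.0 for s in shape], order=3)
    f = f[: shape[0], : shape[1], : shape[2]]
    pad = [(0, shape[i] - f.shape[i]) for i in range(3)]
    f = np.pad(f, pad, mode="edge")
    f = f / max(np.abs(f).max(), 1e-9)
    return 1.0 + amplitude * f


def _mr_fov(spec: PhantomSpec) -> np.ndarray:
    fov = np.ones(spec.shape, dtype=bool)
    cx, cz = spec.mr_crop_vox
    if cx > 0:
        fov[:cx] = False
        fov[-cx:] = False
    if cz > 0:
        fov[..., :cz] = False
        fov[..., -cz:] = False
    return fov


def _finish_modality(clean: np.ndarray, modality: str, spec: PhantomSpec, rng, fov: np.ndarray) -> np.ndarray:
    out = clean.copy()
    if modality in ("T1", "T2") and spec.bias_amplitude > 0:
        out = out * _bias_field(spec.shape, spec.bias_amplitude, rng)
    sig = spec.noise_sigma.get(modality, 0.0)
    if sig > 0:
        out = out + rng.standard_normal(spec.shape) * sig
    return np.where(fov, out, -1000.0 if modality == "CT" else 0.0)


def generate_template(spec: PhantomSpec | None = None, rng: np.random.Generator | None = None) -> TemplateResult:
    """Render the symmetric template subject (deterministic under the seed)."""
    spec = spec or PhantomSpec()
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    labels, shell = _template_labels(spec)
    grid = spec.grid
    mr_fov = _mr_fov(spec)
    ct_fov = np.ones(spec.shape, dtype=bool)
    vols = {}
    for modality, fov in (("CT", ct_fov), ("T1", mr_fov), ("T2", mr_fov)):
        clean = _render(labels, shell, spec, modality)
        vols[modality] = ScalarVolume(grid, _finish_modality(clean, modality, spec, rng, fov).astype(np.float32), fov, modality)
    seg = ProbSegVolume.from_labels(grid, labels, 7)
    record = AtlasRecord("template", vols["T2"], vols["T1"], vols["CT"], seg)
    bone = shell | (labels == LFEM) | (labels == RFEM)
    body = labels > 0
    return TemplateResult(record, labels, bone, body, LabelDictionary())


def random_smooth_displacement(
    spec: PhantomSpec, amplitude_mm: float, rng: np.random.Generator, knots: int | None = None
) -> SpatialTransform:
    """Random coarse-lattice displacement (mm), folding-guarded.

    Coefficients are drawn N(0, amplitude/2) on a coarse knot grid and
    upsampled with a cubic spline; if the resulting map folds (non-positive
    Jacobian on > 1% of voxels) the amplitude is halved and the field
    regenerated.
    """
    knots = knots or spec.deformation_knots
    amp = amplitude_mm
    for _ in range(8):
        coeff = rng.standard_normal((3, knots, knots, knots)) * (amp / 2.0)
        disp = np.stack(
            [ndimage.zoom(coeff[ax], [s / knots for s in spec.shape], order=3, mode="nearest") for ax in range(3)]
        )
        disp = disp[:, : spec.shape[0], : spec.shape[1], : spec.shape[2]]
        pad = [(0, 0)] + [(0, spec.shape[i] - disp.shape[i + 1]) for i in range(3)]
        disp = np.pad(disp, pad, mode="edge")
        m = np.abs(disp).max()
        if m > amplitude_mm:
            disp *= amplitude_mm / m
        T = SpatialTransform(spec.grid, np.eye(4), disp.astype(np.float32))
        if amp == 0 or T.jacobian_positive_fraction() >= 0.99:
            return T
        amp /= 2.0
    return SpatialTransform.identity(spec.grid)


def warp_record(
    template: TemplateResult,
    warp: SpatialTransform,
    spec: PhantomSpec,
    subject_id: str,
    rng: np.random.Generator,
    mr_scale_jitter: float = 0.05,
) -> tuple[AtlasRecord, SubjectTruth]:
    """Warp the noiseless template through ``warp``, then re-apply noise/bias.

    Intensities are resampled linearly and the label map nearest-neighbour,
    so record channels stay mutually consistent.  A per-subject global MR
    scale jitter emulates scanner gain differences.
    """
    grid = spec.grid
    # re-render noiseless channels from template labels, then warp linearly
    labels_t, shell_t = _template_labels(spec)
    lbl_seg = ProbSegVolume.from_labels(grid, labels_t, 7)
    warped_labels = apply_transform_seg(lbl_seg, warp, "nearest").argmax_labels()
    shell_vol = ScalarVolume(grid, shell_t.astype(np.float32), modality="CT")
    warped_shell = apply_transform(shell_vol, warp, "nearest").values > 0.5
    mr_fov = _mr_fov(spec)
    scale = 1.0 + mr_scale_jitter * rng.standard_normal()
    vols = {}
    for modality, fov in (("CT", np.ones(spec.shape, bool)), ("T1", mr_fov), ("T2", mr_fov)):
        clean = _render(labels_t, shell_t, spec, modality)
        wv = apply_transform(ScalarVolume(grid, clean.astype(np.float32), modality=modality), warp, "linear")
        vals = wv.values.astype(np.float64)
        vals[~wv.fov] = -1000.0 if modality == "CT" else 0.0
        if modality != "CT":
            vals *= scale
        vols[modality] = ScalarVolume(grid, _finish_modality(vals, modality, spec, rng, fov).astype(np.float32), fov, modality)
    seg = ProbSegVolume.from_labels(grid, warped_labels, 7)
    rec = AtlasRecord(subject_id, vols["T2"], vols["T1"], vols["CT"], seg)
    bone = warped_shell | np.isin(warped_labels, (LFEM, RFEM))
    truth = SubjectTruth(warp, warped_labels, bone, warped_labels > 0)
    return rec, truth


def generate_cohort(spec: PhantomSpec | None = None, n: int = 8, seed: int | None = None) -> CohortResult:
    """N warped subjects as an atlas database plus one held-out target."""
    spec = spec or PhantomSpec()
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    template = generate_template(spec, np.random.default_rng(rng.integers(2**31)))
    records, truths = [], {}
    for i in range(n):
        warp = random_smooth_displacement(spec, spec.deformation_mm, rng)
        rec, truth = warp_record(template, warp, spec, f"subj{i:02d}", rng)
        records.append(rec)
        truths[rec.id] = truth
    target_warp = random_smooth_displacement(spec, spec.deformation_mm, rng)
    target, target_truth = warp_record(template, target_warp, spec, "target", rng)
    db = AtlasDatabase(records, template.labels)
    return CohortResult(db, target, target_truth, truths, spec)


def misalign_record(
    record: AtlasRecord, amplitude_mm: float, seed: int = 0, spec: PhantomSpec | None = None
) -> MisalignResult:
    """Warp a record's CT (and the CT-side copy of the labels) by a known field.

    Fixture for database-refinement experiments: the T2/T1/segmentation stay
    put, the CT is displaced by a smooth ground-truth warp whose inverse the
    refinement registration should recover.
    """
    if not amplitude_mm >= 0:
        raise ValueError("amplitude must be nonnegative")
    g = record.grid
    spec = spec or PhantomSpec(shape=g.shape, spacing=g.spacing)
    rng = np.random.default_rng(seed)
    warp = random_smooth_displacement(spec, amplitude_mm, rng)
    ct_w = apply_transform(record.ct, warp, "linear")
    vals = ct_w.values.copy()
    vals[~ct_w.fov] = -1000.0
    ct_w = ScalarVolume(g, vals, np.ones(g.shape, bool), "CT")
    ct_seg = apply_transform_seg(record.seg, warp, "nearest")
    rec = AtlasRecord(record.id, record.t2, record.t1, ct_w, record.seg, record.flipped, record.provenance)
    return MisalignResult(rec, ct_seg, warp)
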