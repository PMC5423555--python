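"""Atlas database construction: structure-guided alignment plus pseudo-modality
refinement.

Each subject contributes three image-segmentation pairs (ISPs): T2, T1 and CT,
each with its own manual contours.  The T1 and CT ISPs are registered to the
T2 ISP with a multi-channel cost (LNCC on intensities, KLD on the manual
segmentations), so the contours guide the deformation where intensity alone
is ambiguous.  The CT-to-T2 mapping — the weak link of multi-modal pelvic
registration — is then refined by synthesising a pseudo-CT from the T2 and a
pseudo-T2 from the CT via single-pass multi-atlas fusion, and re-registering
the channel set {T2, T2 contours, pseudo-CT} against {pseudo-T2, CT contours,
CT}: each real channel now has a same-modality partner, while the direct
T2-CT similarity term is kept to preserve the multi-modal correlation.
Left-right flipping doubles the effective atlas count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .fusion import fuse_intensity, rank_atlases, weights_from_ranks
from .image_model import (
    AtlasDatabase,
    AtlasRecord,
    GridMismatchError,
    LabelDictionary,
    ProbSegVolume,
    ScalarVolume,
    left_right_flip,
    read_volume,
    write_volume,
)
from .registration import (
    Channel,
    RegistrationSpec,
    apply_transform,
    register_multichannel,
)
from .similarity import roi_ssim

__all__ = [
    "ImageSegPair",
    "build_initial_record",
    "synthesize_cross_modality",
    "refine_record",
    "build_database",
    "save_database",
    "load_database",
]

log = logging.getLogger("atlasfusion")

#: finest control-point spacings (mm) of the intra-subject registrations;
#: phantom-scale grids scale these down proportionally via `spacing_scale`
T1_TO_T2_SPACING_MM = 2.5
CT_TO_T2_SPACING_MM = 7.5
INTRA_LEVELS = 3


@dataclass
class ImageSegPair:
    """One modality's intensity volume plus its manual contours."""

    intensity: ScalarVolume
    seg: ProbSegVolume
    modality: str

    def __post_init__(self) -> None:
        if not self.intensity.grid.same_grid(self.seg.grid):
            raise GridMismatchError("ISP intensity and segmentation must share a grid")


def _intra_spec(control_mm: float, spacing_scale: float = 1.0, levels: int = INTRA_LEVELS) -> RegistrationSpec:
    return RegistrationSpec(levels=levels, control_spacing_mm=control_mm * spacing_scale, iterations=(40, 20, 10))


def build_initial_record(
    subject_id: str,
    t2_isp: ImageSegPair,
    t1_isp: ImageSegPair,
    ct_isp: ImageSegPair,
    spacing_scale: float = 1.0,
    t1_spec: RegistrationSpec | None = None,
    ct_spec: RegistrationSpec | None = None,
) -> AtlasRecord:
    """Structure-guided alignment of a subject's T1 and CT ISPs to its T2 ISP.

    Raises on registration divergence (the caller decides whether to exclude
    the subject).  The record keeps the T2-based manual contours as its
    segmentation and the estimated mappings under ``record.transforms``.
    """
    t1_spec = t1_spec or _intra_spec(T1_TO_T2_SPACING_MM, spacing_scale)
    ct_spec = ct_spec or _intra_spec(CT_TO_T2_SPACING_MM, spacing_scale)
    res_t1 = register_multichannel(
        [Channel(t2_isp.intensity, t1_isp.intensity, "LNCC"), Channel(t2_isp.seg, t1_isp.seg, "KLD")], t1_spec
    )
    res_ct = register_multichannel(
        [Channel(t2_isp.intensity, ct_isp.intensity, "LNCC"), Channel(t2_isp.seg, ct_isp.seg, "KLD")], ct_spec
    )
    if res_t1.diverged or res_ct.diverged:
        raise RuntimeError(f"intra-subject registration diverged for {subject_id}")
    t1_aligned = apply_transform(t1_isp.intensity, res_t1.transform, "linear")
    ct_aligned = apply_transform(ct_isp.intensity, res_ct.transform, "linear")
    return AtlasRecord(
        id=subject_id,
        t2=t2_isp.intensity,
        t1=t1_aligned,
        ct=ct_aligned,
        seg=t2_isp.seg,
        provenance="initial",
        transforms={"t1": res_t1.transform, "ct": res_ct.transform},
    )


def synthesize_cross_modality(
    target: ScalarVolume,
    pairs: list[tuple[ScalarVolume, ScalarVolume]],
    beta: float = 1.0,
    sigma_g: float = 3.0,
    reg_spec: RegistrationSpec | None = None,
) -> ScalarVolume:
    """Single-pass multi-atlas synthesis of the paired modality.

    ``pairs`` are co-registered (source, paired) volumes whose source modality
    matches the target (T2->CT synthesis passes (T2, CT) pairs; CT->T2 passes
    (CT, T2)).  Each source is registered to the target, the paired volume is
    propagated, atlases are ranked per voxel by the ROI-SSIM of the source
    channel, and the paired volumes fused with exponential rank weights.
    """
    if not pairs:
        raise ValueError("empty synthesis database")
    reg_spec = reg_spec or RegistrationSpec(levels=3, control_spacing_mm=10.0, iterations=(40, 20, 10))
    sims, propagated = [], []
    for src, paired in pairs:
        res = register_multichannel([Channel(target, src, "LNCC")], reg_spec)
        j_src = apply_transform(src, res.transform, "linear")
        j_pair = apply_transform(paired, res.transform, "linear")
        sims.append(roi_ssim(target, j_src, sigma_g))
        propagated.append(j_pair)
    weights = weights_from_ranks(rank_atlases(sims), beta)
    out = fuse_intensity(weights, propagated)
    out.modality = "pCT" if propagated[0].modality in ("CT", "pCT") else propagated[0].modality
    return out


def refine_record(
    record: AtlasRecord,
    ct_isp: ImageSegPair,
    pct: ScalarVolume,
    pt2: ScalarVolume,
    spacing_scale: float = 1.0,
    spec: RegistrationSpec | None = None,
) -> AtlasRecord:
    """Refine the CT-to-T2 alignment with pseudo-modality channels.

    Fixed channel set {T2, T2 contours, pseudo-CT} versus moving
    {pseudo-T2, CT contours, CT}; the direct T2-CT pair is preserved as an
    extra LNCC channel.  The refinement warm-starts from (and therefore
    composes with) the record's existing global CT mapping; only the CT
    channel of the record is updated.
    """
    spec = spec or _intra_spec(CT_TO_T2_SPACING_MM, spacing_scale)
    channels = [
        Channel(record.t2, pt2, "LNCC"),
        Channel(pct, ct_isp.intensity, "LNCC"),
        Channel(record.t2, ct_isp.intensity, "LNCC"),  # preserved multi-modal term
        Channel(record.seg, ct_isp.seg, "KLD"),
    ]
    res = register_multichannel(channels, spec, init=record.transforms.get("ct"))
    ct_aligned = apply_transform(ct_isp.intensity, res.transform, "linear")
    transforms = dict(record.transforms)
    transforms["ct_initial"] = record.transforms.get("ct")
    transforms["ct"] = res.transform
    return AtlasRecord(
        id=record.id,
        t2=record.t2,
        t1=record.t1,
        ct=ct_aligned,
        seg=record.seg,
        flipped=record.flipped,
        provenance="refined",
        transforms=transforms,
    )


def build_database(
    subjects: list[tuple[str, ImageSegPair, ImageSegPair, ImageSegPair]],
    labels: LabelDictionary | None = None,
    refine: bool = True,
    augment_flip: bool = True,
    spacing_scale: float = 1.0,
    beta: float = 1.0,
    sigma_g: float = 3.0,
    t1_spec: RegistrationSpec | None = None,
    ct_spec: RegistrationSpec | None = None,
) -> AtlasDatabase:
    """Build the full atlas database from per-subject (T2, T1, CT) ISPs.

    Initial structure-guided records first; if ``refine``, leave-one-out
    pseudo-CT / pseudo-T2 synthesis (over the *initial* records — the refined
    set does not exist yet) followed by per-subject refinement; if
    ``augment_flip``, each record's left-right mirror is appended.
    """
    labels = labels or LabelDictionary()
    initial: list[AtlasRecord] = []
    ct_isps: dict[str, ImageSegPair] = {}
    for sid, t2_isp, t1_isp, ct_isp in subjects:
        try:
            rec = build_initial_record(sid, t2_isp, t1_isp, ct_isp, spacing_scale, t1_spec=t1_spec, ct_spec=ct_spec)
        except RuntimeError as exc:
            log.warning("subject %s excluded from the database: %s", sid, exc)
            continue
        initial.append(rec)
        ct_isps[sid] = ct_isp
    records = initial
    if refine:
        synth_spec = RegistrationSpec(levels=3, control_spacing_mm=10.0 * spacing_scale, iterations=(40, 20, 10))
        refined = []
        for rec in initial:
            others = [r for r in initial if r.id != rec.id]
            if not others:
                refined.append(rec)
                continue
            pct = synthesize_cross_modality(
                rec.t2, [(r.t2, r.ct) for r in others], beta=beta, sigma_g=sigma_g, reg_spec=synth_spec
            )
            ct_isp = ct_isps[rec.id]
            # (CT, T2) pairs come from the initially aligned records: their CT
            # and T2 channels are co-registered on the T2 grid
            pt2 = synthesize_cross_modality(
                ct_isp.intensity,
                [(r.ct, r.t2) for r in others],
                beta=beta,
                sigma_g=sigma_g,
                reg_spec=synth_spec,
            )
            refined.append(refine_record(rec, ct_isp, pct, pt2, spacing_scale))
        records = refined
    if augment_flip:
        records = records + [left_right_flip(r, labels) for r in records]
    return AtlasDatabase(records, labels)


# ---------------------------------------------------------------------------
# On-disk database layout: one directory per record + a YAML manifest.


def save_database(db: AtlasDatabase, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"labels": db.labels.to_yaml_dict(), "records": []}
    for rec in db.records:
        rdir = out_dir / rec.id
        rdir.mkdir(exist_ok=True)
        write_volume(rec.t2, rdir / "t2.nii.gz")
        write_volume(rec.t1, rdir / "t1.nii.gz")
        write_volume(rec.ct, rdir / "ct.nii.gz")
        np.save(rdir / "seg_prob.npy", rec.seg.probabilities)
        prov = {"id": rec.id, "flipped": rec.flipped, "provenance": rec.provenance}
        with open(rdir / "provenance.yaml", "w") as fh:
            yaml.safe_dump(prov, fh)
        manifest["records"].append(prov)
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


def load_database(db_dir: str | Path) -> AtlasDatabase:
    db_dir = Path(db_dir)
    with open(db_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    labels = LabelDictionary.from_yaml_dict(manifest["labels"])
    records = []
    for entry in manifest["records"]:
        rdir = db_dir / entry["id"]
        t2 = read_volume(rdir / "t2.nii.gz", "T2")
        t1 = read_volume(rdir / "t1.nii.gz", "T1")
        ct = read_volume(rdir / "ct.nii.gz", "CT")
        probs = np.load(rdir / "seg_prob.npy")
        seg = ProbSegVolume(t2.grid, probs)
        records.append(
            AtlasRecord(entry["id"], t2, t1, ct, seg, flipped=entry["flipped"], provenance=entry["provenance"])
        )
    return AtlasDatabase(records, labels)
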