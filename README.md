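# atlasfusion

Joint multi-atlas organ segmentation and pseudo-CT synthesis from structural
MR images, for MRI-only radiotherapy planning workflows in the pelvis.

Radiotherapy dose calculation needs electron-density information that MR does
not provide. Given a database of atlases — subjects with co-registered
T2-weighted MR, T1-weighted MR, CT and manually contoured organs —
`atlasfusion` maps every atlas onto a new patient's MR images and fuses the
propagated CT intensities and organ labels into a *pseudo-CT* (in Hounsfield
units) and a probabilistic segmentation, jointly and consistently: one
per-voxel weight field drives both fusions, so a voxel labelled bone receives
a bone-like density.

## Method

At iteration *t* the target state is the pair of MR images plus the previous
pseudo-CT and segmentation. Each atlas *n* is deformably registered to that
state (local normalised cross-correlation for image channels,
Kullback–Leibler divergence for label channels), propagated, and scored per
voxel by a local similarity

LSIM = ROI-SSIM(T2) + ROI-SSIM(T1) + ROI-SSIM(pCT<sub>t−1</sub>, CT<sub>n</sub>) + LDSC(S<sub>t−1</sub>, S<sub>n</sub>),

where ROI-SSIM is the structural similarity computed through
density-normalised convolution (so partially overlapping fields of view do
not bias the local moments) and LDSC is a local fuzzy Dice between smoothed
label probabilities. At the first iteration only the MR terms exist. Atlases
are ranked per voxel and weighted `w = exp(−β_t · rank)` with `β_t`
decreasing by 0.125 from 1; the fused outputs are

pCT(x) = Σ w<sub>n</sub>(x) CT<sub>n</sub>(x) / Σ w<sub>n</sub>(x)   and   S(x, l) ∝ Σ w<sub>n</sub>(x) V<sub>n</sub>(x, l),

with V the propagated label votes. The atlas database itself is built by
structure-guided intra-subject registration (contours as KLD channels) and
then refined by synthesising a pseudo-CT from each subject's T2 and a
pseudo-T2 from its CT, giving every channel a same-modality partner in a
final multi-channel registration. Left-right flipping doubles the database.

Because no clinical cohort ships with the package, a synthetic pelvic phantom
module generates ground-truth cohorts ({T2, T1, CT, labels} with known
inter-subject warps, MR bias fields, noise, and differing MR/CT fields of
view) on which every component is validated.

## Worked example

```python
from atlasfusion.phantom import PhantomSpec, generate_cohort
from atlasfusion.pipeline import RunConfig, run
from atlasfusion import evaluation

cohort = generate_cohort(PhantomSpec(shape=(48, 48, 48)), n=4, seed=11)
cfg = RunConfig.phantom_scale(n_iterations=2)
result = run(cohort.target.t2, cohort.target.t1, cohort.db, cfg)

body = evaluation.body_mask_from_ct(cohort.target.ct)
mae, me = evaluation.mae_me(result.pct, cohort.target.ct, body)
dice = evaluation.fuzzy_dice(cohort.target.seg, result.seg_prob, 2)  # bladder
print(f"MAE {mae:.1f} HU, ME {me:.1f} HU, bladder fuzzy Dice {dice:.3f}")
```

prints

```
MAE 36.3 HU, ME -5.3 HU, bladder fuzzy Dice 0.944
```

meaning the synthesised CT deviates from the held-out subject's true CT by
36.3 HU on average inside the body (a water-only baseline sits near 130 HU on
this phantom), with a small negative bias, and the fused bladder contour
overlaps the ground truth at fuzzy Dice 0.94.

The same pipeline is available from the shell:

```bash
atlasfusion phantom --n 8 --size 64 --seed 7 --out work/
atlasfusion run --target-t2 work/target/t2.nii.gz --target-t1 work/target/t1.nii.gz \
                --db work/db --out work/out
atlasfusion evaluate --pct work/out/pct.nii.gz --ref-ct work/target/ct_reference.nii.gz \
                --out work/metrics.csv
```

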