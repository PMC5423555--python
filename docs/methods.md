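# Methods

This note records the models, the numerical choices and the open design
decisions behind `atlasfusion`, and what the synthetic-phantom validation
does and does not demonstrate.

## Image model

Volumes live on regular 3-D grids (0-based voxel indices; physical mm
coordinates through origin, spacing and direction cosines). Every intensity
volume carries a binary field-of-view (FOV) mask Ω, because the MR and CT
acquisitions of one subject genuinely cover different physical extents
(different couches and scan lengths); all similarity machinery treats
missing coverage explicitly rather than as zero-valued signal. Two volumes
interoperate only when their grids agree within a relative tolerance of
1e-5, or through an explicit spatial transform — nothing resamples silently.
Segmentations are stored as per-voxel label probability vectors (one-hot for
manual contours); categorical maps are derived views with ties broken toward
the lower label index. The default label dictionary is
{0 background, 1 prostate, 2 bladder, 3 rectum, 4/5 left/right femur head,
6 body}, with the femur heads declared as left/right homologues so flip
augmentation can swap them.

Isotropic resampling uses cubic-spline interpolation by default; the target
spacing is configuration (no single value is canonical — it should match the
CT slice spacing of the cohort at hand). Intensity non-uniformity correction
is a pluggable hook (a caller-supplied volume→volume function), not a bundled
algorithm.

## Local similarity over irregular FOVs

Local moments are computed by density-normalised convolution: with a
Gaussian kernel G (σ_G = 3 voxels by default, truncated at 3σ, separable),

μ_I = G∗(I·Ω) / G∗Ω,  σ_I² = μ_{I²} − μ_I²,  σ_{IJ} = μ_{IJ} − μ_I μ_J,

which makes the windowed statistics unbiased up to the FOV boundary. Where
the smoothed density G∗Ω falls below 1e-12 the moments are undefined and the
voxel is marked invalid; variances are clamped at ≥ 0 (tolerance 1e-9).
σ_G is interpreted in voxels (the literature leaves the unit ambiguous);
it is configurable.

ROI-SSIM is the product of the standard SSIM luminance and structure terms
built from these moments. The stabiliser constants default to the usual
C₁ = (0.01·D)², C₂ = (0.03·D)² with D the per-modality dynamic range — fixed
at 2000 HU for CT-like images, and the robust 1st–99th percentile range
inside the FOV for MR (MR units are scanner-arbitrary, so a fixed D would be
meaningless). Scores live in [−1, 1] inside the joint FOV and are −∞
outside; the sentinel is paired with an explicit validity mask so no NaNs
enter downstream arithmetic.

The local fuzzy Dice (LDSC) smooths each label's probability map with G and
sums 2·min(a,b)/(a+b) over labels. Two conventions had to be fixed: a label
with zero smoothed mass in both images contributes 0 (absent organs must not
inflate similarity), and the background label is excluded by default
(otherwise the dominant background term swamps organ agreement); both are
configurable.

The combined LSIM is the plain sum of the two MR ROI-SSIM terms and, from
the second iteration, the pseudo-CT ROI-SSIM term and the LDSC term.
Optional per-channel weights (default 1) exist because the terms have
different ranges — see "Channel balance" below.

## Fusion

At each voxel, atlases with finite LSIM are ranked by descending similarity
(ties toward the lower atlas index, making results deterministic) and
weighted w = exp(−β·r) with rank r starting at 0 — so the best atlas always
has weight 1 and the fusion collapses to best-atlas copy as β → ∞ and to the
unweighted mean as β → 0. All finite-LSIM atlases contribute (no top-K cut;
one is available behind configuration). β follows the schedule
β_t = 1 − 0.125·(t−1), floored at 0.125: early iterations trust only the
locally best atlases, later ones average more broadly as registration
improves. Votes are one-hot indicators from nearest-neighbour-propagated
labels (a fuzzy-vote mode using interpolated probabilities exists behind
configuration). One weight field drives both the intensity and the label
fusion — this is the consistency guarantee: tissue class and synthesised
density cannot disagree systematically, because they are the same convex
combination of the same atlases. Voxels where no atlas is valid are filled
by policy: air (−1000 HU) outside a body mask when one is supplied, nearest
fusable value otherwise, and pure background in the segmentation.

## Registration (reference backend)

The registration contract is a symmetric global stage followed by a
multi-channel non-rigid stage minimising the weighted sum of channel costs
(LNCC for images, KLD for label posteriors, probabilities clamped at 1e-6).
The bundled backend is a modest free-form optimiser designed for
phantom-scale volumes, not a clinical registration engine; an external
engine can be plugged in by exchanging dense displacement fields.

Global stage: Powell search over translation / rigid / 9-parameter affine at
the two coarsest pyramid levels, warm-started level to level. The affine
objective uses normalised mutual information (32 bins) for intensity
channels — NMI is modality-agnostic and, unlike local-correlation scores,
has no degenerate optimum that crushes an axis to inflate local agreement —
plus a mass-normalised label SSD for segmentation channels so that organ
misalignment is not diluted by the empty majority of the volume. The
symmetric variant estimates both directions and averages in the log-affine
sense.

Non-rigid stage: demons-style dense displacement updates, coarse-to-fine.
Intensity channels are locally standardised (zero local mean, unit local
variance, std floored at 5% of its FOV mean) so that sum-of-squares forces
ascend the LNCC; channels pairing different contrasts (T2–CT, T1–T2) use a
sign-adaptive force that follows |LNCC| — the residual is taken against +F
or −F according to the sign of the local correlation, and vanishes where
the correlation magnitude is below 0.1 — because cross-contrast anatomy is
locally anti-correlated as often as correlated (bone is bright on CT, dark
on T2). Label channels contribute per-label probability-SSD forces on
Gaussian-softened (σ = 1 voxel) maps; raw one-hot steps alias badly under
interpolation. Each channel's force field is rescaled by its 99.5th
percentile magnitude before the weighted sum, so a channel with sparse,
sharp residuals cannot drown out the others. The summed force is smoothed
(fluid regularisation, width control_spacing/2), applied with a trust-region
step of 0.45 of the finest voxel size, and the accumulated field is smoothed
again (elastic, width control_spacing/4) — the Gaussian pair plays the role
a bending-energy penalty plays in lattice-parametrised registration, with
`control_spacing_mm` setting the deformation scale. Per level, the best
displacement under a surrogate cost is kept, with patience-based early
stopping; a level that never improves on its starting cost flags the run as
diverged (the best-so-far transform is still returned). Everything is
deterministic.

The KLD channel force is a gradient surrogate (probability SSD), while the
*reported* cost is the exact clamped KLD; the two agree at the optimum
(F = M) and empirically track each other on phantoms.

## Pipeline

Iteration t registers every atlas to the current target state (MR channels
only at t = 1; MR + previous pseudo-CT + previous labels at t ≥ 2),
propagates intensities linearly and labels nearest-neighbour, computes LSIM,
ranks, weights with β_t, and fuses. Registrations warm-start from the
previous iteration's transforms (cold start available). A registration that
fails or diverges drops its atlas from that iteration's fusion with a
warning; only if every atlas drops does the run fail. Four iterations is the
default; two capture most of the gain on phantoms.

### Channel balance (decided open question)

The LSIM sum is formally unweighted, but its terms have incommensurate
ranges: each ROI-SSIM term varies within a few hundredths around 1 between
plausible atlases, while the LDSC term moves in steps of order 1 per label.
On the synthetic phantom, whose organs are piecewise-constant, intensity
carries no texture inside organs and the quantised LDSC term then *decides*
the ranking almost everywhere, favouring atlases that agree with the
previous consensus; measured on held-out phantom subjects this blurs the
synthesised CT (MAE up 5–9%) for no segmentation gain. Similarly,
full-weight pseudo-CT/label channels inside the t ≥ 2 registration drag
every atlas toward the previous estimate. The phantom-scale preset
(`RunConfig.phantom_scale`) therefore sets the LDSC ranking weight to 0 and
the auxiliary registration channels to weight 0.3, while the general default
(`RunConfig()`) keeps every term at weight 1 as the method defines. On real
anatomy, where intensity retains discrimination inside soft tissue, the
balance is expected to matter much less; the weights are ordinary
configuration.

## Atlas database building

Initial records: the T1 and CT image–segmentation pairs are registered to
the T2 pair with LNCC + KLD channels (3 pyramid levels; finest control
spacing 2.5 mm for T1→T2 and 7.5 mm for CT→T2 at clinical resolution, scaled
proportionally on coarser phantom grids). Refinement: with a leave-one-out
database of *initial* records (the refined set does not exist yet), a
pseudo-CT is synthesised from each subject's T2 and a pseudo-T2 from its CT
by single-pass multi-atlas fusion ranked by ROI-SSIM on the source modality;
the channel set {T2, T2 contours, pseudo-CT} is then registered to
{pseudo-T2, CT contours, CT}, keeping the direct T2–CT pair as an extra
channel (LNCC with the sign-adaptive multimodal force — no specific measure
is canonical for that preserved term; a mutual-information variant would be
a reasonable alternative). The refinement warm-starts from the initial CT
mapping, so the global stage composes rather than being re-estimated, and
only the record's CT channel is updated — T2, T1 and the contours are
untouched. Flip augmentation mirrors records about the mid-sagittal plane
and swaps the lateral label pair.

## Evaluation

Fuzzy Dice 2Σmin(p,q)/Σ(p+q) per label (reduces to hard Dice on one-hot
input; undefined → NA when a label is absent from both). Modified Hausdorff
distance: max of the two directed mean nearest-neighbour distances between
boundary point sets, in mm; boundaries are mask voxels with a face-adjacent
(6-connectivity) background neighbour, volume edges counting as background.
MAE/ME in HU over a region of interest. NMI = (H(I)+H(J))/H(I,J) over the
joint FOV with 64 bins (NA for single-bin images). The water-only baseline
thresholds the reference CT to a body contour, fills holes in 3-D, and sets
the body to 0 HU over −1000 HU air; on calibrated HU the default threshold
is −500 (a literal +500 only makes sense for offset-intensity encodings and
is available via configuration).

## Synthetic phantom

The phantom is a laterally symmetric pelvis-like template: an elliptical
body long in z, a pelvic bone shell, paired femur heads, bladder, prostate
and a rectum modelled as a bent tube, rendered to CT (air −1000, soft
tissues 10–40, trabecular bone 700, cortical shell 1000 HU) and to T1/T2
contrasts via per-tissue tables (e.g. urine bright on T2, dark on T1), with
additive Gaussian noise (15 HU CT, 4 a.u. MR), a 15% smooth multiplicative
MR bias field, and an MR FOV cropped by 4 columns and 6 slices per side
relative to the full CT FOV. Cohort subjects are the template warped by
independent coarse-lattice displacements (5 mm amplitude, folding-guarded by
halving on non-positive Jacobians) with per-subject MR gain jitter; the true
warps are retained as registration oracles. Default grids are 64³ at 3 mm —
a deliberately scaled-down pelvis chosen so that full leave-one-out studies
run on a single CPU in minutes; the study sizes used by the tests and the
acceptance script (cohorts of 3–8 subjects at 40³–64³, two pipeline
iterations) are the package's standard phantom conditions.

Deformations are drawn from the same coarse-lattice family the registration
optimises, deliberately: a recovery failure then indicates an implementation
bug, not model mismatch. Conversely, passing on phantoms does not
demonstrate clinical-grade registration: real pelvic anatomy has texture,
sliding interfaces, bowel gas and couch differences the phantom does not
model, and the reference optimiser makes no claim of equivalence to
production registration engines.

## Known limitations

- The reference registration backend is phantom-grade; clinical use is
  expected to plug in an external engine through the displacement-field
  interface.
- The LSIM channel balance on textureless images is degenerate (see above);
  the phantom preset works around rather than solves this.
- The refinement updates only the CT alignment; the T1→T2 mapping is kept
  from the initial stage.
- Dose calculation and DVH analysis are out of scope; the pseudo-CT is
  evaluated in HU error terms only.
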