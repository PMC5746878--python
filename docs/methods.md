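# Methods

## The measurement chain

`pulmoquant` quantifies pulmonary vascular redistribution and parenchymal
attenuation on contrast-enhanced inspiratory chest CT. The chain is:
lung extraction → lobar labeling → vessel detection → per-subject metrics
→ cohort statistics. Every stage is deterministic; every random element of
the synthetic data derives from an explicit seed.

### Lung extraction

Air-like voxels (HU < −320) not connected to the volume border are
labeled; the two largest components become the lungs (a single fused
component is split at the mid-body sagittal plane with a warning).
Contrast-filled vessels appear as holes and are recovered per lung by
morphological closing (ball, radius 2 voxels) followed by 3D hole
filling; filling runs per lung so the closing cannot bridge the
mediastinal gap. Laterality comes from component centroids (x increases
toward the patient's right). The airway tree is not explicitly removed;
trachea and main bronchi are excluded only when they connect to border
air. This is a deliberate simplification of a full anatomical
segmentation stage and is the main deviation from clinical-grade
segmenters.

### Lobar labels

An externally supplied lobe map (e.g. from a dedicated lobe segmenter, or
phantom ground truth) is clipped to the lung mask; if more than 1% of its
labeled voxels fall outside the mask it is rejected as misaligned.
Without one, a geometric fallback splits each lung at half its
cranio-caudal extent into upper/lower (no middle lobe). When lobar
segmentation cannot separate the middle lobe, `merge_problem_lobes` folds
ML into RUL. The provenance flag (`external` / `fallback` / `merged`)
travels into the metrics table so cohort statistics can stratify.

### Vessel detection

Candidate voxels are lung voxels with HU **≥** threshold (inclusive, so
integer-HU edge cases are deterministic). The standard threshold is
−500 HU. When the mean lung density falls outside [−850, −600] HU the
threshold adapts: the mode of the lung HU histogram at 1-HU binning
(ties toward the lower HU) plus 360 HU, clamped to [−650, −200] HU. The
offset is calibrated so a normal parenchymal mode near −860 HU reproduces
the −500 standard; the rule may fall below −500 in very lucent lungs, and
the per-subject threshold and adaptive flag are always recorded.

Candidates are grouped into 3D connected components (26-connectivity by
default; 6 and 18 available) and components with volume ≤ 100 mm³ are
removed entirely. Volumes are voxel counts × voxel volume; the filter is
strict (a 104 mm³ component survives, a 96 mm³ one does not). Each
retained component is assigned a lobe by majority vote of its voxels'
labels, ties toward the lobe with the more cranial centroid; per-lobe
*volumes*, however, are integrated voxelwise (each vessel voxel counts
toward its own lobe), so lobar totals are exactly conservative.

An optional body-size correction multiplies vessel volumes by
1.73 / BSA_DuBois (BSA = 0.007184 · weight^0.425 · height^0.725). It
defaults to off (factor 1.0) and is a reporting multiplier only: the
100 mm³ filter always acts on uncorrected geometric volume.

### Densitometry and derived metrics

Mean density and percentiles are computed over the full lung mask,
vessels included (whole-lung densitometry convention); a vessels-excluded
variant is a flag. The percentile estimator interpolates linearly between
closest ranks: rank r = 1 + (p/100)(n−1) over the sorted values. p10 is
the primary attenuation metric; p15 and the LAA-950 fraction (voxels
< −950 HU) are carried as optional emphysema-style indices. Vascular
density = vessel volume / lung volume is computed per subject (group
tables average the per-subject ratios, not the ratio of group means).
Lobar ratios RUL/RLL, LUL/LLL and ULs/LLs = (RUL+LUL)/(RLL+LLL) exclude
the middle lobe unless it was merged into RUL; a zero denominator makes
the ratio missing, never infinite.

### Cohort statistics

Welch's t-test is the default two-group comparison (safer under unequal
variances and group sizes; Student's pooled variant is available for
fidelity checks). Normality screening uses Shapiro–Wilk; correlation with
mPAP uses Pearson's r with the t-transform p-value. ROC curves are built
over all distinct thresholds with higher score ⇒ PH; AUC is trapezoidal
(equal to the Mann–Whitney pairwise statistic with ties counted 0.5), and
the reported cutoff maximizes Youden's J with ties broken toward higher
specificity (an accuracy-maximizing criterion is selectable). No
multiple-testing correction is applied; the rendered report says so.

## The phantom generator

The phantom emulates the statistical structure the analysis rests on, not
photorealistic anatomy: an air background (−1000 HU), a soft-tissue body
shell (+40 HU, padded to keep at least two voxels of shell around the
lungs), two ellipsoidal lungs with Gaussian parenchyma
(mean −850 HU, SD 40), ellipsoidal oligemia patches (mean shift −80 HU),
a bifurcating vessel tree rendered at +150 HU (contrast-enhanced regime),
and additive Gaussian noise (SD 20 HU). Lobes are geometric partitions of
each lung by axial pseudo-fissure planes (right: RLL below 45% of the
lung's height, ML to 60%, RUL above; left: LLL below 55%).

The vessel tree grows one bifurcating subtree per lobe from a medial
hilar seed. Child radii follow Murray's law (ratio 2^(−1/3)), lengths
shrink by 0.72 per generation, siblings leave on opposite sides of the
parent axis, and all endpoints stay inside the (convex) lobe region, so
segment midpoints provably lie in their assigned lobe. Segments keep a
pleural clearance of ~1.1× their radius — computed with an exact
point-to-ellipsoid distance, since axis-shrinking erosion overestimates
lateral clearance near the apex of an elongated ellipsoid — so rasterized
vessels never breach the pleura (a breach would open the vessel "hole" to
the outside air and defeat hole filling). Fissure planes require no such
clearance; real vessels cross fissures too.

Radii are calibrated so each lobe's **expected occupied volume** matches
its allocation target: a Monte-Carlo estimate of the cylinder-union
volume (sampling points inside the cylinders and weighting by
multiplicity) corrects the double-counting of junction overlap in the
plain cylinder sum, and the growth/calibration loop repeats until the
pleural margins cover the calibrated radii. The allocation itself sends
`apical_fraction` of the total vessel volume to the upper lobes (split
equally RUL/LUL) and the rest to the lower lobes; the middle lobe carries
no tree, so the ground-truth ULs/LLs ratio is f/(1−f).

### Cohort parameters

A two-arm cohort draws per-subject parameters from group distributions
(truncated to [0, 1]):

| parameter | control | PH-like | rationale |
|---|---|---|---|
| apical fraction | 0.35 ± 0.065 | 0.54 ± 0.20 | means give truth ULs/LLs of 0.54 and 1.17, the published magnitudes of the redistribution effect; SDs derived from the reported ratio dispersions by the delta method f = r/(1+r) — tight in controls, wide in PH |
| oligemia fraction | 0 | 0.15 ± 0.05 | clinical reports do not quantify oligemic extent; 0.15 of the parenchyma with a −80 HU shift reproduces the direction and rough size (~25 HU) of the p10 group difference |
| lung scale | 0.95 ± 0.05 (clipped to [0.85, 1.05]) | same | between-subject lung-size variability; above 1.05 the lungs would breach the body shell |

Per-subject seeds derive deterministically from the cohort seed; the same
cohort spec reproduces the cohort voxel for voxel.

### What the phantom does not emulate

No partial-volume effects at vessel boundaries (vessel voxels are set
exactly to +150 HU), no beam hardening, streaks, motion, cardiac
chambers, airway lumina, or anatomically realistic fissures. Consequently
vessel voxels are perfectly separable from parenchyma at the −500 HU
threshold, and parameter recovery on default phantoms is essentially
exact — recovery tests therefore validate the *logic* of the chain
(masking, connectivity, filtering, lobar integration, unit conversions),
not its robustness to scanner physics. Passing them says nothing about
performance on real CT with partial-volume blur or calibration drift.

## Numerical choices

- Threshold comparison inclusive (≥); histogram mode ties toward lower HU.
- Component filter strict (> 100 mm³ retained).
- Percentiles: closest-ranks linear interpolation, computed in float64.
- ROC cutoff ties → higher specificity; degenerate all-tied scores give
  AUC 0.5 by construction of the curve.
- Ratios with zero denominators are `None`/NaN, excluded pairwise in
  cohort summaries with the post-exclusion n reported.
- Rasterization marks a voxel as vessel when its center lies inside a
  flat-capped cylinder; for radii ≥ 2 voxels the rasterized volume is
  within 15% of the analytic cylinder sum (junction overlap accounts for
  most of the gap).
- The infeasibility guard rejects volume targets whose calibrated root
  radius exceeds 0.35× the smallest relevant lobe dimension, rather than
  silently under-filling.

## Problem sizes

Unit tests run mostly on 96³ (1.8 mm) and 64³ (2.0 mm) phantoms; the
parameter-recovery experiments use the default working resolution of
128³ at 1.4 mm (vessel radii ≥ 2 voxels), ten seeds; redistribution
monotonicity uses five apical fractions × three seeds at 96³ (30 cm³
target, five tree generations, vascular density ≈ 0.03); the in-silico
study uses 8 + 8 subjects at 96³ with a 24 cm³ vessel target, and its
null-calibration band uses five cohort seeds at 64³. These sizes were
chosen to keep the full validation suite comfortably runnable on a
laptop-class single CPU.

## Limitations

- The geometric fallback lobe split (cranio-caudal midpoint) is crude; on
  real data an external lobe segmentation should be supplied, and the
  provenance flag should be checked before interpreting lobar ratios.
- The adaptive-threshold offset (+360 HU) is a calibration to the normal
  parenchymal mode, not a published algorithm; it is exposed in
  `PipelineConfig` for sensitivity analysis.
- Published cohort effect sizes for these metrics come from patient
  populations with heterogeneous disease; the phantom arms reproduce the
  direction and rough magnitude of group differences, not their clinical
  variance structure.
- Artery/vein separation, vessel radius spectra and airway quantification
  are out of scope.
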