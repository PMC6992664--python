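# Methods

This note records the models, parameter choices and numerical decisions
behind `ctseg`, and what the synthetic phantoms do and do not establish.

## Scope and assumptions

Inputs are 3-D head CT volumes in Hounsfield units, already rigidly aligned
to a common grid with a known mid-sagittal column (exposed as
`midsagittal_index`, defaulting to the central column). Spatial
normalisation, DICOM ingestion, gantry-tilt and bias corrections are out of
scope; volumes are reoriented on load to a fixed left-right /
posterior-anterior / inferior-superior axis order because every symmetry and
slice-wise operation assumes a known left-right axis and an axial slice
axis. The reference cohort must share the test volume's lattice.

## Intensity conditioning

* **Clamp and bone strip.** Voxels below 0 HU are clamped to 0; voxels at or
  above 100 HU are excluded from the brain domain. All later stages operate
  inside the domain mask. The bone threshold is applied on raw HU, before
  the contrast transform.
* **Tissue–CSF contrast transform.** A monotone piecewise-linear map expands
  the 0–40 HU window by a gain of 1.5 (0–40 → 0–60) and compresses 40–100 HU
  linearly onto 60–100, leaving 100 HU fixed. The gain was chosen from the
  guide-value arithmetic: it places CSF (~8 HU → 12) below the 14 HU sulci
  guide, the chronic-lesion band (~15 HU → 22.5) between the ventricle
  guides and the lesion-sensitive classes, and white matter (28 → 42) in the
  parenchyma classes. The window and gain are configurable, so a different
  published transform can be substituted. A strictly contrast-expanding
  monotone map cannot also be idempotent (an idempotent monotone map is the
  identity on its range), so idempotence is not claimed for this stage.
* **TV denoising.** The ROF objective `½‖u−f‖² + w·TV(u)` is minimised with
  Chambolle's dual projection (step τ = 1/12, 6-neighbour forward
  differences, intensities normalised by 100 HU). Iteration stops when the
  relative objective change falls below `tv_tol` (1e-4) or after
  `tv_max_iter` (200) iterations; non-convergence is recorded in provenance
  and the current iterate returned. The default weight 0.02 puts the
  fidelity scale at ~2 HU — the CT noise amplitude — because a larger weight
  visibly erodes the 15–20 HU lesion/parenchyma contrast at 3 mm voxels.
  During the solve, out-of-domain (bone) voxels are set to the bone
  threshold so the 800 HU skull edge cannot bleed halo into parenchyma; they
  are restored afterwards.
* **Top-hat healthy map.** A morphological white top-hat with an
  anisotropy-aware ellipsoidal ball (radius 10 mm converted to voxels per
  axis) is thresholded at 5 HU of response. It flags parenchyma that is
  locally bright relative to adjacent CSF spaces; on the phantom it is
  nearly empty because the synthetic parenchyma is homogeneous, and its role
  there is only to prove the subtraction plumbing.

## MFMC clustering

Voxels are assigned to classes anchored at fixed guide intensities by
minimising the Potts energy (absolute-deviation data term by default;
squared optional). The pairwise penalty is `reg_weight × face area (mm²)`
between 6-neighbours (26-connectivity optional with distance-scaled
weights), making the boundary cost a surface energy that does not bias
against the thick-slice direction. Default `reg_weight = 0.1`: at 3 mm
voxels this prices a boundary face at ~0.9 HU, comparable to noise-induced
data-term fluctuations; a weight of 1.0 would price faces at 9 HU, larger
than the typical inter-class data margin, and collapses whole lesions into
the parenchyma class.

Two labels are solved exactly with one s-t min cut; more labels use
alpha-expansion (each move a min cut, labels visited in ascending guide
order so results do not depend on the configured guide order), sweeping
until no move lowers the energy. Capacities are scaled to integers for the
max-flow solver with an adaptive scale bounded by the int32 budget; moves
are accepted only if the exact float energy decreases, so rounding can never
worsen the labeling. On exhaustively enumerable instances the achieved
energy matches the global optimum (acceptance suite, 200 random instances).

The returned per-class maps blend the hard labeling (weight 0.6) with a
normalised inverse-distance relaxation of the data costs (weight 0.4):
values are soft, sum to one in-domain, and the argmax always reproduces the
optimised labeling. Binarisation thresholds a class map at
`prob_threshold = 0.5`, which therefore equals the hard-label mask.

Guide values: sulci pass (14, 24, 34 HU, lowest class binarised), ventricle
pass (20, 27 HU, lower class binarised then mirror-congruence filtered),
lesion-sensitive pass (10, 20, 34 HU — two classes in the transformed
encephalomalacia/gliosis band, the top class anchoring parenchyma
consistently with the sulci pass; the candidate map is the union of the
sub-parenchymal classes).

## Watershed clustering

Each axial slice is partitioned independently by a watershed of the
in-plane gradient magnitude (central differences over mm coordinates),
seeded from regional minima after h-minima suppression with depth 1 HU —
about half the expected noise amplitude, deep enough to merge pure-noise
basins while tissue boundaries (≥ 4 HU/mm ridges) keep their own
catchments. Mask-level clustering keeps or drops whole regions by occupancy
(≥ 50% by default, the same rule at map regularisation and at mask fusion).
The fusion watershed is computed from the contrast-transformed image
*before* TV denoising: denoising widens boundary rings, and at 3 mm voxels
the widened ring dilutes lesion-basin occupancy below the 50% rule.

## Zeta anomaly mapping

For feature vector `x` and references `r_1..r_n`, zeta is the mean distance
from `x` to its k nearest references minus the mean pairwise distance among
those k neighbours (Euclidean metric; may be negative). Voxel features are
the raw post-transform intensity patches of radius 1 (3×3×3), with
symmetric edge padding; HU is a calibrated scale, so no per-subject
standardisation is applied beyond the shared transform. Defaults k = 5,
patch radius 1.

The binary zeta mask thresholds the map and excludes sulci and ventricle
voxels. The default threshold is calibrated from the cohort itself: the
99th percentile of in-domain scores pooled over leave-one-out self-scoring,
so the operating point is fixed by lesion-free data alone and adapts to the
cohort's noise and registration jitter. An absolute threshold can be set in
config.

## Mask assembly

Mask 1 = lesion-sensitive candidate map minus the union of the three
(watershed-regularised) non-lesion maps, minus connected components that
both touch the medial paraventricular zone and cross the mid-sagittal
plane. "Medial paraventricular" is operationalised geometrically: within
4 mm of the ventricle mask and closer to the mid-sagittal plane than the
nearest ventricle voxel. Mask 2 = thresholded zeta map outside sulci and
ventricles. The union of both is clustered against the fusion watershed at
50% occupancy; components smaller than 5 voxels, or confined to one axial
plane while larger than 100 voxels, are removed. An empty final mask is a
valid result (lesion-free scan). The pipeline is fully deterministic.

Results are emitted on the native grid plus a 4×4×4 mm analysis grid
(scalar maps by bin averaging, masks by fractional occupancy with ties at
0.5 kept — conservative toward lesion retention).

## Outcome modelling

Outcomes are dichotomised as: modified Rankin Scale 0–2 vs 3+ (pre-admission
and discharge), NIHSS increase > 2 points at 24 h, and sex (passthrough,
used as a quality-control target). Records lacking a required field are
excluded with a reason.

Feature tiers grow hierarchically: age; + comorbidities (diabetes,
hypertension, atrial fibrillation, congestive heart failure); + total
lesion volume; + flattened analysis-grid lesion mask; + mask and zeta map
concatenated; and gray/white tissue-map features for the sex model. Voxel
features are flattened in C order of the canonical axes, so feature j is
the same anatomical location for every subject.

Classification uses an rbf-kernel SVM with stratified k-fold (k = 10)
cross-validation and a grid search over cost 2⁻⁵…2¹⁵ and kernel width
2⁻¹⁵…2³ (powers of 4); the selection criterion is the fold-averaged AUROC,
computed on the same folds that are reported. This mirrors a protocol in
which grid search is *not* nested, and the reported CV AUROC is therefore
mildly optimistic; a nested protocol can be layered on by the caller.
Features are min-max scaled to [0, 1] on each training fold. AUROC is the
Mann-Whitney concordance with ties counted half; confidence intervals are
class-stratified bootstrap percentiles (n = 1,000 by default) of the pooled
out-of-fold scores; paired model comparison is the DeLong test (two-sided,
p = 1 for identical score vectors). With fixed seeds every quantity is
bit-reproducible.

## Phantom generator

The phantom emulates the geometry the segmentation relies on: an
ellipsoidal head with a 6 mm skull shell at 800 HU, a gray-matter shell
(36 HU) over a white-matter core (28 HU), bilaterally symmetric
CSF ventricles (8 HU), eight radial sulcal CSF bands in the outer cortical
band, optional ellipsoidal lesion inserts (15 HU) stamped into parenchyma
only, and additive Gaussian noise (2 HU). Truth masks are recorded before
noise. Cohort members get per-subject geometry jitter (default 1 mm) and
independent noise. The default grid is 64³ at 3 mm — coarse enough that the
full pipeline runs in seconds-to-minutes on one CPU, fine enough that an
8 ml lesion spans ~300 voxels.

The synthetic outcome table draws ages from Normal(73, 15) truncated to
[18, 100] and comorbidity indicators at acute-stroke-cohort prevalences
(diabetes 27.6%, hypertension 64.8%, atrial fibrillation 24.8%, CHF 7.2%,
male 50%); the binary outcome follows a logistic model on age and lesion
volume with configurable log-odds effects.

What the phantom does *not* emulate: cortical folding, partial-volume
anatomy at sub-voxel scale, beam hardening and streak artifacts, scanner
resolution anisotropy (3–5 mm slices vs 0.3 mm in-plane), registration
error beyond rigid jitter, and the heterogeneous texture of real gliosis.
Passing the phantom suite therefore demonstrates the internal consistency
and contracts of the pipeline — not clinical-grade accuracy on hospital
scans, which can only be established against expert manual segmentations.

## Problem sizes used in the test and acceptance runs

Phantom recovery uses the default 64³ grid with one ~8 ml lesion and an
8-member cohort. Solver oracles use exhaustively enumerable instances
(≤ 3×3×2 voxels, 2–3 labels; 200 instances) and brute-force zeta/AUROC
checks (500 and 200 instances). The modelling protocol is calibrated with
200 null replicates (n = 400) for the DeLong type-I error and 20 planted-
effect replicates (n = 120) for the tier comparison. These sizes were
chosen so the whole suite reruns comfortably on a single CPU.

## Known limitations

* The watershed fusion is sensitive to voxel size: at coarse grids the
  boundary ring of a lesion is a large fraction of its basin, which is why
  the fusion uses the sharper pre-denoising image.
* The zeta map reflects any deviation from the cohort — including atrophy
  and registration imperfections — not only focal lesions; the cohort-
  calibrated threshold absorbs the cohort's own jitter but not pathology
  systematically absent from it.
* The cohort-calibrated threshold requires cohort size > k + 1 for
  leave-one-out scoring.
* Alpha-expansion guarantees a strong local optimum, not the global one,
  for ≥ 3 labels; on enumerable instances it attains the global optimum,
  and the acceptance suite enforces a 1% energy band.
* The analysis grid is labelled "MNI" in output filenames by convention;
  no actual nonlinear normalisation is performed — inputs are assumed
  co-registered.
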