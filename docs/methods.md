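# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic cohort generator

The generator emulates a triple-negative breast-cancer cohort of 125
patients (66 ALNM, 59 non-ALNM by default) with three co-registered
sequences (T2WI, DWI, DCE) at 1 mm isotropic spacing, a tumor mask, a
second-rater mask and a clinical table. It is a pure function of its config:
a fixed seed yields byte-identical volumes and tables.

**Clinical covariates.** Continuous covariates are drawn from
class-conditional normals whose targets are the reference cohort's class
summaries (e.g. ALN length 18.4 ± 11.9 mm in ALNM vs 5.0 ± 5.9 mm in
non-ALNM; Ki-67 dichotomized at 20%). Where a physical floor applies
(lengths, lipids) draws are clipped and the pre-clip location is
moment-matched by root finding, so the *post-clip* class mean equals the
target — otherwise truncation would bias, for instance, the non-ALNM ALN
length upward by ~0.7 mm. Categorical covariates (TIC type, BI-RADS, grade,
Ki-67, menopause) use the class-conditional level frequencies of the same
table. Labels are drawn first at the exact configured class balance and
covariates are drawn class-conditionally; this directly controls the
class-conditional moments that the calibration tests assert, which a
label-from-covariates logistic link would not.

**Tumor geometry and habitats.** Tumors are ellipsoids (radius from the
patient's tumor length, clipped to the grid) with a smoothed random
boundary. Habitats are thick lateral sub-lobes: tumor voxels are ordered
along a random direction and cut at quantiles, so each habitat is a compact,
near-contiguous region whose thickness scales with the tumor radius.
Concentric shells are available (`habitat_geometry="concentric"`) but at
desk-scale tumor sizes the outer shells are thinner than the sliding window
used downstream, which blurs adjacent habitats into a continuum; the lateral
layout keeps the habitat-count question well posed at every scale. The
volume fraction of the last (high-DCE) habitat is the primary planted class
signal: mean 0.22 (SD 0.07) in non-ALNM vs 0.36 (SD 0.08) in ALNM.

**Intensities.** Each habitat has a distinct multiparametric signature
(z-score-scale units): the necrotic-type habitat is T2-bright and
unenhancing, the hypercellular habitat DWI-bright, the vascular habitat
DCE-bright. The signatures are deliberately non-collinear — each habitat
stands out in a different sequence — because collinear signatures (habitat 2
midway between 1 and 3 on every channel) make the cluster count
unidentifiable in principle. Texture is spatially correlated Gaussian noise
(correlation length 0.75 mm) whose amplitude differs per habitat *and per
sequence*, again forming a non-collinear pattern. Adjacent habitats blend
over ~2.5 mm via distance-decay weights, as tissue interfaces do; sharp
interfaces would create a spurious "boundary" phenotype in window-based
features. Background tissue carries unit-SD correlated noise so that the
per-patient whole-volume z-score scale is stable across tumor sizes.
In ALNM tumors the vascular habitat additionally enhances more
(`dce_mean_shift`, default +0.28) and is more heterogeneous (`noise_scale`,
default ×1.18) — an angiogenic-aggressiveness reading that places class
signal in the habitat's own intensity and texture, not only in its volume.
The effect sizes are set so the desk-scale regime is mid-range rather than
at the AUC ceiling, where the relative ordering of near-perfect models is
pure noise.

**Second rater.** The rater-2 mask displaces the boundary locally: the
signed distance to the tumor surface is perturbed by a smooth random field
scaled by the morphological radius (default 1 mm), then a fraction of
boundary voxels is flipped (default 0.2). Local displacement, rather than a
global dilation or erosion, mirrors how a second reader actually deviates
and avoids biasing every whole-tumor feature in one direction per patient.
Default settings keep the Dice overlap in roughly 0.90–0.96; the
perturbation never empties the mask (that is an error).

**Split.** Label-stratified: the training set holds `floor(0.7·n)` patients
with per-class quotas `floor(0.7·n_class)` and remainders assigned by
largest fractional part. At 66/59 this yields exactly 87/38.

**What the generator does not model.** Pharmacokinetic DCE dynamics, coil
or bias-field artifacts, scanner differences, registration error, DICOM
metadata. Passing tests therefore demonstrate internal correctness and
recoverability of planted structure, not performance on clinical data.

## Preprocessing

Fixed order: resample → clip → z-score. Resampling uses SimpleITK (linear
for images, nearest-neighbor for masks; output shape
`ceil(shape·spacing_in/spacing_out)`, shared origin at voxel 0). Clipping
percentiles default to (0.5, 99.5) inside the tumor VOI — the conventional
outlier trim; they are configurable because the reference procedure does not
pin them. The z-score scope defaults to the whole volume (configurable to
the VOI); the population (1/N) SD convention is used everywhere in the
package. A zero-variance scope is an error naming the patient and sequence.

## Habitat model

*Local features*: per sequence, windowed mean, SD and entropy (16-bin
tumor-wide discretization) in a 3³ window intersected with the tumor mask —
9 channels. Windowed skewness, kurtosis and energy are implemented but off
by default: third/fourth moments from 27 voxels are noise-dominated and,
once standardized to unit variance, act as pure-noise dimensions that dilute
the silhouette criterion.

*Supervoxels*: SLIC on the standardized channels (compactness 0.1), masked
to the tumor, with connectivity enforced; the target granularity is one
supervoxel per 100 mm³ of tumor. Pooling is the arithmetic mean of member
voxel vectors (an exact identity, tested).

*Clustering*: pooled supervoxels from **all training patients** are
standardized and clustered with one K-means (k-means++ with 10 restarts,
fixed seed) for k = 2…10; the mean silhouette selects K with ties broken
toward smaller k. A single population-level model guarantees that habitat
labels mean the same thing in every patient; test patients are assigned by
nearest centroid. Clusters are ordered by ascending centroid DCE local-mean
intensity, so habitat 1 is always the least-enhancing and habitat K the
most-enhancing subregion. Habitats may be empty in a given patient (a
recorded count of zero, not an error).

## Feature bank

The 1,037-per-(sequence, region) layout is: 14 shape + 93 × 11, with the 93
intensity features = 18 first-order + 24 GLCM + 14 GLDM + 16 GLRLM +
16 GLSZM + 5 NGTDM, and the 11 images = original + 8 wavelet subbands +
2 LoG scales. "Eight decomposition levels" is implemented as the 8 subbands
of a single-level stationary 3D wavelet transform (coif1) — the standard
radiomics convention, and the only reading consistent with the 1,037 count.
LoG responses are scale-normalized (σ²·∇²G, σ in mm). Shape features are
computed once, on the original geometry only (marching-cubes mesh for
surface/volume, PCA axis lengths, projected maximum 2D diameters).

Discretization is fixed-bin-count (default 32) inside each region; fixed bin
*width* is ill-posed after z-scoring. Texture conventions: GLCM and GLRLM
are computed per direction over the 13 unique 3D offsets and the feature
values averaged; GLSZM zones and GLDM dependencies use 26-connectivity (the
GLDM dependence index is 1 + the number of neighbors within α = 0 gray
levels); gray levels absent from a region are dropped, so level-count
dependent features use the levels actually present. Degenerate regions use
fixed fallbacks (GLCM correlation = 1, MCC = 1, IMC1 = IMC2 = 0, inverse
variance = 0, NGTDM contrast = 0 at one level). Regions below
`min_region_voxels` (default 10) yield missing-flagged vectors — every value
NaN plus a reason — never silent NaNs; such columns are dropped at the start
of the selection cascade.

Two numerical facts documented because tests rely on them: marching-cubes
meshes of digitized spheres overestimate surface area by several percent
(staircase effect), and sampled LoG kernels do not integrate exactly to
zero, so the response to a constant volume is ~10⁻³ of the input value
rather than 0.

## Selection cascade

Stages nest; every statistic is computed from training rows only (an
instrumented assertion; flipping test-row values changes nothing). ICC is
the two-way random-effects, absolute-agreement, single-rater form ICC(2,1),
implemented from the ANOVA mean squares and vectorized across features;
zero between-subject variance returns 0 by convention. Rater-2 feature
tables repeat the full extraction with the second mask, including habitat
re-assignment under the same fitted model. The univariate stage gates
Welch's t vs Mann–Whitney U on Shapiro–Wilk normality in both classes
(α = 0.05) and applies no multiple-testing correction. Spearman pruning is
greedy in ascending univariate-p order, keeping the most outcome-relevant
member of each correlated block. mRMR is the FCQ variant (F-statistic
relevance over mean |Pearson| redundancy, ties by feature name) with
k = 30 by default. The LASSO stage scans 40 log-spaced penalties with
stratified 10-fold CV and picks the minimum mean binomial deviance (not the
1-SE rule); survivors are the nonzero coefficients of the refit.

## Models

Clinical covariates are screened by univariable logistic regression against
stated reference levels (TIC: inflow/platform; BI-RADS: 4a4b; grade: G1–2;
Ki-67: <20%); variables with p < 0.05 enter the multivariable fit, whose
significant terms form the clinical model's features. Two small-sample
fallbacks keep the clinical model defined at desk scale (recorded as flags):
if no term stays jointly significant the screened set is used, and if
nothing passes the screen the single best-screening variable is used. For a
single binary covariate the logistic MLE odds ratio equals the 2×2
cross-product ratio — asserted in tests and used to re-derive the published
univariable odds ratios from their cell counts.

The four XGBoost classifiers share a grid (depth {2,3,4} × learning rate
{0.05,0.1,0.3} × trees {50,100,200} × subsample {0.8,1.0} by default)
scanned exhaustively under 5-fold stratified CV on mean validation AUC; ties
prefer fewer trees, then shallower depth. The winner is refit on the full
training split. The combined model uses the fusion-pool cascade survivors
plus the clinical covariates; residual missing values are median-imputed on
the training split. Gradient boosting itself is treated as an exchangeable
engine (binary logistic objective, deterministic under a seed), not
re-derived.

## Evaluation

AUC is the tie-adjusted Mann–Whitney statistic; its variance and the paired
test use DeLong's placement-value construction with a two-sided normal
approximation and no multiplicity correction across model pairs.
Hosmer–Lemeshow uses deciles of predicted risk (ties kept in one bin, empty
bins merged), statistic Σ(O−E)²/(E(1−E/n_g)), df = groups − 2. Decision
curves report NB(p_t) on a 0.01–0.99 grid with treat-all and treat-none
references; model net benefit can exceed neither the prevalence nor, as an
identity, be asserted above the references. Confusion metrics at the 0.5
threshold report undefined ratios as explicit nulls.

## Interpretation

Attributions come from the exact polynomial-time tree-Shapley algorithm
built into xgboost, in log-odds (margin) space with the path-dependent
(training-cover) expectation; local accuracy — base value plus attributions
equals the margin output — is asserted at explanation time. An independent
exhaustive enumerator over the model's JSON dump (2^M subsets, cover-weighted
conditional expectations) serves as a validation oracle. The two routes
coincide to numerical precision whenever no root-to-leaf path splits twice
on the same feature; for repeated features the engine merges the path
entries, which redistributes credit between the occurrences while leaving
totals unchanged. Oracle-equivalence tests therefore run on models verified
repeat-free (stump ensembles; an interaction tree), and deep models assert
total agreement. Branch decisions are reproduced in float32, matching the
engine.

## Desk-scale study conditions

Two seed-replicated properties are computed at reduced problem sizes chosen
once as desk-scale replication conditions:

* **Information ordering** (combined ≥ habitat ≥ clinical in expected test
  AUC): ten cohorts of 60 patients on 28³ grids, the unfiltered feature
  bank (original image only), mRMR k = 15, 5-fold LASSO and a two-point
  boosting grid. The full-scale defaults (125 patients, 48³ grids, 11
  filtered images) remain the pipeline defaults.
* **Habitat-count recovery** (modal silhouette-selected K = 3 over five
  seeds): ten patients on 40³ grids with one supervoxel per 150 mm³ and the
  class-dependent habitat modulation switched off, so every tumor carries
  the same three pure signatures — the strong-contrast condition under
  which the cluster count is the only question being asked. Larger tumors
  matter here because the fraction of supervoxels straddling a habitat
  interface shrinks with tumor radius.

## Known limitations

* The generator's habitats are geometric constructs with stationary
  Gaussian textures; real habitat imaging contends with perfusion dynamics,
  partial-volume mixtures and registration error.
* Silhouette-based K selection is only as identifiable as the planted
  contrast; near-collinear signatures or interface-dominated supervoxel
  populations legitimately favor other K.
* The hand-authored feature bank follows the common radiomics definitions
  of its families but has not been benchmarked against an external
  reference implementation in this environment; its correctness rests on
  the closed-form, brute-force and invariance tests in the suite.
* Table-level performance numbers from the reference cohort (AUCs around
  0.66–0.81) are not reproducible targets — the cohort is private — and are
  treated only as an ordering property on synthetic data.
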