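# Methods

`glioradiomics` implements a complete multiregional radiomics analysis chain
for predicting IDH1 mutation status in glioblastoma from multiparametric MRI
(T1w, T1c, T2w, FLAIR), evaluated end-to-end on synthetic phantom cohorts.
This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic experiments do and do not show.

## Synthetic phantom cohorts

Real multicenter GBM imaging with subregion segmentations and genotypes
cannot be redistributed, so the package generates digital phantoms carrying
the structure the analysis depends on.

**Geometry.** Each tumor is four nested ellipsoids on a 64×64×64 grid at
1 mm isotropic spacing (necrosis ⊂ non-enhancement ⊂ enhancement ⊂ edema),
with per-case jitter on the shared center (±2 mm) and on the semi-axes
(±6 % shared, ±2 % per region).  Default semi-axes (mm): necrosis
(5, 4.5, 4), non-enhancement (9, 8, 7.5), enhancement (13.5, 12, 11), edema
(20, 18, 16.5).  The concentric topology guarantees all four regions exist
and matches the ring-like appearance of enhancing tumors with central
necrosis and surrounding edema.  A spherical "head" mask (radius 29 mm)
carries normal-tissue intensity and defines the mask for intensity
landmarks.

**Intensities.** Each (region, channel) pair has a fixed mean in arbitrary
units on a 0–110 scale chosen to mimic qualitative MR contrast (bright
enhancement on T1c, bright edema on T2w/FLAIR, dark necrosis on T1w/T1c),
plus additive Gaussian noise (SD 2.0).

**Class effect.** The imaging literature gives no quantitative account of how
IDH1-mutated tumors differ radiologically, so the planted effect sizes are
free parameters of the generator, not biological claims.  Mutated cases
differ in two ways, so both geometry and texture features carry signal:
their non-enhancement semi-axes are scaled ×1.30 and necrosis ×0.72
(altered subregion proportions), and the Gaussian-random-field texture
added to the enhancement area on T1c/T2w (amplitude 10) has autocorrelation
length 2.2 voxels instead of 0.7.  The defaults are deliberately strong —
the end-to-end experiments test that the pipeline *can* recover a planted
signal, not how small a signal it can detect.

**Imbalance and clinical covariates.** IDH1 labels are Bernoulli draws with
prevalence 0.09, the published mutation frequency scale in GBM cohorts.
Age (normal, mean 54, SD 13, clipped to 9–85), sex (60 % male), KPS
(50–100, mode 80) and tumor location (frontal/temporal-dominant categorical)
mirror published cohort demographics and are drawn independently of the
class, so the clinical model is a true null reference by default.

**Scanner drift.** Each case receives a strictly monotone intensity
distortion `f(x) = a·sign(x)|x|^γ + b` with per-case a ∈ [0.8, 1.25],
b ∈ [−8, 8], γ ∈ [0.85, 1.2], emulating cross-scanner variation.

**What the phantoms do not model:** anatomy, bias fields beyond monotone
drift, mis-segmentation, partial-volume effects, or any real covariance
between clinical factors and genotype.  Tests passing on phantoms show the
*computational chain* is correct and leakage-free; they say nothing about
discrimination on real patients.

## Intensity standardization

Landmark-based piecewise-linear histogram standardization: landmarks are the
deciles plus the 1st/99th percentiles (12 landmarks) of the masked (head)
voxels.  Training volumes are linearly rescaled so their outer landmarks hit
[0, 100]; the standard scale is the mean of the rescaled landmarks.  A new
volume is mapped by piecewise-linear interpolation from its own landmarks to
the standard values, with linear extrapolation beyond the outer landmarks.
Percentiles are affine-equivariant, so any affine scanner drift is undone
exactly; general monotone drift is corrected at the landmarks and
approximately between them.  Landmarks use masked voxels only because
background would otherwise dominate the histogram.

## Gray-level quantization

Intensities are quantized to 64 levels by a Lloyd-Max quantizer: alternating
centroid/boundary updates on the empirical distribution (1-D Lloyd/k-means),
stopping when the relative MSE improvement falls below 1e-7 or at 500
iterations.  The quantizer is seedless: it runs from two deterministic
initializations — equal-mass quantiles (robust for heavy tails) and
equal-width midpoints — and keeps the lower-MSE run.  The second init's
first iteration *is* uniform-width binning, so the final MSE never exceeds
the uniform-binning benchmark; the equal-mass init alone can converge to a
worse local optimum on bimodal inputs.  Inputs with fewer distinct values
than levels map each distinct value to its own level with zero error.

The quantizer is fitted per (case, channel) on the whole-tumor voxels and
shared by all six regions of that case, so a gray level means the same thing
in every subregion of one tumor.  Whether quantization should be per-region
or per-tumor is genuinely open; per-tumor was chosen for comparability.

## Regions and the feature catalog

Six extraction regions: the four base subregions plus tumor core
(necrosis ∪ non-enhancement ∪ enhancement — everything but edema) and whole
tumor (core ∪ edema).  Non-tumor tissue never enters a mask.

The full catalog has exactly 1614 features:

| block     | count | composition |
|-----------|-------|-------------|
| location  | 2     | region (7 categories), side (3), fixed integer codes |
| geometry  | 28    | 10 shape descriptors × {core, whole tumor} + {volume, proportion} × 4 base subregions |
| intensity | 336   | 14 first-order statistics × 6 regions × 4 channels |
| texture   | 1248  | (GLCM 21 + GLRLM 13 + GLSZM 13 + NGTDM 5) × 6 regions × 4 channels |

The geometry allocation is a reconstruction: the total of 28 is fixed but
its split across regions is not published, so the package uses the only
allocation of the published shape-feature names that reaches 28 without
inventing new descriptors.  GLCM Homogeneity and Informational Measure of
Correlation each have two published variants and are counted twice, giving
the 21-feature GLCM set.  "Busyness" appears as "Business" in some published
feature lists; a name-alias map preserves the correspondence.

**Geometry numerics.** Surface area is exact boundary-face counting of the
voxel mask.  This makes the cube closed form exact (a 10³ voxel cube has
A = 600 mm², sphericity ≈ 0.806) but over-estimates smooth surfaces by a
factor approaching 3/2 (staircase effect), so digitized-ball sphericity
converges to 2/3 rather than 1 — a documented property, not a bug.  Longest
diameter is the maximum pairwise distance between convex-hull vertices of
surface-voxel centers; solidity is volume over convex-hull volume (clipped
to 1); eccentricity is √(1 − λ_min/λ_max) of the voxel-coordinate
covariance; compactness is V/(√π·A^{3/2}); spherical disproportion is
1/sphericity.  Coordinates are 0-based voxel centers scaled by the spacing.

**Intensity numerics.** Population moments; skewness/kurtosis are 0 by
convention for constant input; kurtosis is the raw standardized fourth
moment (not excess).  Entropy (bits) and uniformity use the 64-level
quantized histogram inside the pipeline so first-order and texture features
share one alphabet; standalone calls fall back to a 64-bin equal-width
histogram.

**Texture numerics.** All matrices use 26-connectivity as 13 unique unit
offsets.  GLCM is direction-merged (counts summed over offsets, each ordered
pair counted both ways, then normalized); GLRLM is per-direction with
features averaged over the 13 matrices; GLSZM zones are 26-connected
components; NGTDM uses the mean of in-mask neighbors and excludes voxels
with no in-mask neighbor.  The merged-GLCM / averaged-GLRLM conventions are
fixed, documented choices where the original in-house implementation is
unknown.  Degenerate denominators: variance-normalized features (GLCM
correlation, NGTDM busyness/strength with empty support) are 0; NGTDM
coarseness is capped at 1e9 (ε = 1e-9).  The GLRLM implementation uses the
window-count identity (runs of length exactly ℓ = c_ℓ − 2c_{ℓ+1} + c_{ℓ+2}
for uniform-window counts c) for vectorization; tests verify it against an
explicit run-scan oracle.

**Missing regions.** An empty base subregion yields volume 0 and proportion
0 (the region is genuinely absent) but missing (NaN) intensity and texture
values; missing values are median-imputed with training-cohort statistics
before modeling.

## Balancing (SMOTE)

Training tables only.  The minority class is raised to 64 instances
(published protocol; with 10 minority training cases that is 54 synthetic
rows) by interpolating `x + u(x_nn − x)`, u ~ U[0,1), between a minority
seed row (cycled round-robin) and one of its k = 5 nearest minority
neighbors.  Neighbor search uses Euclidean distance on z-scored radiomics
columns (training statistics); k = 5 follows the original SMOTE publication since
the protocol leaves it unstated.  Clinical and categorical columns of
synthetic rows are copied from the seed instance.  Distance ties break by
lowest row index; everything is seeded.  The pipeline balances the full
training table once, so all model configurations see the same synthetic
cases.

## Feature selection (Boruta)

All-relevant selection: each iteration appends one independently permuted
shadow copy of *every* original feature, fits a random forest (300 trees,
Gini split criterion, √p features per split), and scores importance as the
per-tree Gini importance Z-scored across trees.  An undecided feature
scores a hit when its importance exceeds the maximum shadow importance.
After each iteration a two-sided binomial test against p = 0.5 (Bonferroni
over the undecided features, α = 0.05) confirms or rejects; the loop stops
at 100 iterations or when nothing is undecided.  Remaining tentative
features are resolved by comparing their median importance with the median
max-shadow importance.

The full shadow pool (rather than shadows of undecided features only) is a
deliberate choice: with a shrinking pool the max-shadow null weakens late in
the run, and features whose only "signal" is chance in-sample structure
begin to beat it systematically.  Keeping the pool at full strength holds
the false-positive rate at the nominal level throughout; the cost is
conservatism on very wide tables (1614 candidates with ~170 balanced
training rows), which the pipeline absorbs by falling back to the top-5
median-importance features when a configuration's selection comes back
empty.  Direct model training on an explicitly empty feature set remains an
error.

## Models and evaluation

Nine configurations: four single-region models (enhancement,
non-enhancement, necrosis, edema), tumor core, whole tumor, all-region, a
clinical model (age, sex, KPS only — no selection), and a combined model
(all-region + clinical candidates through Boruta jointly).  Every classifier
is a 300-tree Gini random forest; the probability score is the forest's
mutated-class probability.  Determinism comes from explicit seeds at every
stage, all recorded in the provenance block.

Evaluation reports ACC/SEN/SPE/PRE and F1 at the Youden-index cutoff
(max SEN + SPE − 1 over midpoint candidate thresholds, ties toward the lower
threshold / higher sensitivity), the ROC curve and its AUC with midrank tie
handling (equal to the Mann-Whitney statistic and to the DeLong placement
AUC), and the precision-recall curve.  The cutoff is fixed on the training
cohort by default and carried to validation; re-optimizing on the evaluated
cohort is available behind a flag because the original protocol does not say
which was done.  Paired AUCs are compared with the fast midrank DeLong
estimator; identical score vectors return statistic 0 and p = 1 by
convention.  Rounded report tables use two decimals.

**Leakage policy.** Standardization scales, imputation medians, SMOTE, and
Boruta see the training cohort only; train/validation case-id disjointness
is asserted at run time.

## Problem sizes in tests and the acceptance script

Unit tests run on 24³ phantoms with proportionally scaled radii (and a
higher prevalence of 0.35 with relaxed SMOTE targets, so cohorts of ~30
cases still contain enough minority cases for the neighbor search).  The
texture oracle suite uses 100 random blocks up to 6³ with an 8-level
alphabet, where exhaustive enumeration is tractable.  The selection-recovery
suite uses the planted design (1 informative + 30 noise features, n = 300)
over 20 seeds; noise columns are class-mean-balanced by construction so that
any confirmation is a selector false positive rather than a data-level
chance association.  The end-to-end experiment uses 120 training / 100
validation phantoms at the full 64³ grid with the default planted effect —
the cohort-size scale of the published study — and compares the all-region
model against the clinical null model.  The acceptance script repeats that
experiment with seeds derived from its `--seed` argument and additionally
advances a cohort seed deterministically in the (rare) event that a draw
leaves fewer than three mutated training cases, which would make SMOTE's
neighbor search impossible.

## Known limitations

* Phantom realism is deliberately minimal; absolute performance numbers on
  phantoms do not transfer to patient data.
* The landmark map inverts affine drift exactly but general monotone drift
  only at the landmarks.
* Boruta on p ≫ n tables is conservative with full-pool shadows; the
  published 8-feature all-region selection on real data is not a
  reproducible target and is not asserted anywhere.
* GLRLM direction handling (averaged) and the geometry allocation are
  documented reconstructions of unpublished implementation details.
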