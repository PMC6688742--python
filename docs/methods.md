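# Methods

## Model and assumptions

The analysis treats the metabolic panel and the voxelwise GMV maps as two
blocks measured on the same subjects and asks for the pair of linear
combinations with maximal cross-block covariance. With both blocks
column-standardized, the solution is the SVD of the p×v cross-product
`XᵀY = UΔVᵀ`; the r-th pair of latent variables is `Lx_r = X u_r`,
`Ly_r = Y v_r`. The decomposition is computed economy-size on the p×v
matrix (p ≤ 10 here), so memory scales with p·v and no v×v object is ever
formed. Successive pairs satisfy the exact bi-orthogonality
`Lx_rᵀ Ly_s = δ_r·1[r=s]`; within-block score correlations are *not* zero in
general, and the package makes no claim that they are.

SVD signs are arbitrary. Components are oriented so that the metabolic
latent score correlates positively with the raw BMI column (the "higher
adiposity" orientation common in this literature); `flip=True` returns the
mirrored solution, which is equally valid. Tied singular values are kept in
stable index order and flagged, since the spanned subspace is then
non-unique.

## Preprocessing

Order: exclusion filters → natural-log transform of CRP, IL6, adiponectin
and leptin → OLS residualization (age + sex for the panel; age + sex + TIV
per voxel) with intercept → column standardization (sample SD, N−1). The
log base is irrelevant after standardization; natural log is used. Whether
standardization precedes or follows residualization is not identifiable
from the conventions of the field; the order fixed here (residualize, then
standardize) keeps residuals exactly orthogonal to the confounds, which the
tests assert to 1e−8. Voxels enter the analysis when the gray-matter
probability image reaches 0.3; columns follow raster order of the mask so
cluster coordinates are reproducible. Constant voxels are dropped with a
trace rather than standardized.

## Resampling inference

*Permutation.* Only X rows are permuted (permuting both blocks by the same
permutation is a row relabeling and provably leaves Δ unchanged — tested).
The permuted singular values are sorted and compared rank-by-rank to the
observed ones; the printed formula `p = #(null > observed)/B` is used
without add-one smoothing, so `p = 0` means "below 1/B" and is displayed as
such. A Wilks-style sequential variant is intentionally not the default;
rank-by-rank pairing is the documented choice.

*Bootstrap.* Subjects are resampled jointly in X and Y and each replicate's
blocks are re-standardized. Replicate axes can swap and reflect, so each
bootstrap decomposition is aligned to the original by greedy matching on
the p-dimensional side (largest |uᵀu| first, sign from the matched inner
product); a full orthogonal Procrustes rotation is available behind a flag
and off by default. The per-weight SE over aligned replicates gives the
bootstrap ratio `Z = w/SE`, thresholded at 2.3. SEs below machine noise
(e.g. noiseless rank-one data) would send Z to infinity; Z is capped at ±50
and flagged. Resamples with a constant predictor column are redrawn and
counted.

*Clusters.* `|Z| > 5` voxels are grouped by 26-neighbor connectivity
(6-neighbor selectable), each cluster reporting size, peak |Z|, the weight
at the peak and the peak's mm coordinates via the image affine; clusters are
sorted by size. Labeling is verified against a brute-force flood fill.

*Cross-validation.* Twenty 80/20 splits; confound coefficients and column
means/SDs are estimated on the training set and applied to the test set
before projection (the no-leakage reading of "project onto the raw test
data"; a literal raw-matrix option exists for comparison). The inner
permutation p is one-sided on the signed correlation, since the sign
convention makes the alternative directional; a two-sided option is
provided. Splits are unstratified, drawn without replacement.

## Synthetic cohorts

The generator emulates what the analysis needs to be tested against:

* **Marginals** from published cohort summaries of older adults (e.g. BMI
  27.7 ± 4.1 kg/m², age 60–79, 55.6% male); right-skewed assays (CRP, IL6,
  adiponectin, leptin) are log-normal with moments matched on the raw
  scale; IL6 is left-censored by clamping at the 1.5 pg/ml detection limit
  (censoring-as-clamping, not missingness — the censored value is the
  limit itself, which is also how the sensitivity filter identifies it).
* **Confounding**: age, sex and TIV act on both blocks (effect sizes in SD
  units per standardized confounder), added *after* the latent structure so
  residualization is genuinely required for recovery.
* **Planted structure**: a shared standard-normal latent score t enters the
  panel through a unit vector u_true with coefficient
  γ = sqrt(ρ/(1−ρ)) and the voxel block through a smooth-blob unit pattern
  v_true. Spatially smoothed noise is correlated along v_true, which would
  dilute the realized latent correlation; the voxel-side signal is therefore
  scaled by sqrt(vᵀKv) (K the smoothed-noise covariance, computed exactly
  from the Gaussian filter), so that corr(X u_true, Y v_true) = ρ by
  construction. Multiple components are Gram–Schmidt-orthogonalized within
  each block.
* **Smoothness**: voxel noise is Gaussian-filtered at a configurable FWHM
  (default 8 mm at 2 mm voxels) and renormalized to unit pointwise variance.
* **Cognition**: raw CERAD-style test scores (fluency counts, TMT times,
  word-list counts) with a chosen standardized slope of each domain
  composite on the latent score; counts are rounded and floored at zero, and
  TMT-B is built as TMT-A times a positive ratio so B ≥ A always.

What the generator does **not** emulate: cortical anatomy, registration
error, non-Gaussian voxel noise, site effects, and realistic inter-predictor
correlation structure beyond what the shared latent component induces
(published bivariate correlations of such panels exist only in supplementary
material and are not calibrated here). Passing tests therefore demonstrate
statistical correctness of the machinery under the stated generative model,
not robustness to real-data pathologies.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately chosen scales: the
recovery checks use the study-like condition ρ = 0.5, N = 500, p = 9,
v ≈ 2000 (default grid 22×22×11 at 2 mm, mask 2020 voxels), 500
bootstraps; permutation calibration uses 200 independent-block replicates of
N = 100, p = 5, v = 200 at 500 permutations; cross-validation checks use 20
splits with 200 inner permutations, with the population latent correlation
measured on an independent 100 000-subject cohort. Resampling defaults in
the library itself remain 2000 permutations / 2000 bootstraps / 1000 inner
permutations, the values a full analysis would use.

Other numerical decisions: sample SD (N−1) throughout; singular values are
tied when they differ by less than 1e−10 relative; residualization uses
`lstsq` (never explicit inverses) and refuses rank-deficient confounds;
zero-variance columns raise rather than silently producing NaN; all
randomness flows through named per-stage substreams of a single root seed,
so every stage is independently reproducible and two runs with the same
config are bit-identical.

## Known limitations

* The "metabolic score is a better predictor than BMI alone" comparison
  computes total GMV as the in-mask voxel sum times voxel volume; a
  surface-based segmentation total would differ by a roughly constant
  factor and offset, which the TIV adjustment and standardized betas absorb.
* Bootstrap alignment is greedy, not globally optimal; at very low SNR with
  near-tied singular values the axis assignment can be unstable (the
  Procrustes option mitigates this at the cost of mixing axes).
* The cluster table carries no anatomical labels (no atlas dependency).
* Explained-covariance fractions are computed from the full singular-value
  set of the fitted rank; they are undefined (NaN) when all singular values
  vanish.
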