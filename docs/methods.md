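# Methods

This note documents the models implemented in `radiophen`, their
assumptions, the parameter choices that matter, and what the synthetic
cohorts do and do not establish about behavior on real data.

## Feature extraction

**Resampling.** Heterogeneous voxel spacings are harmonized by
resampling every image/mask pair to the component-wise minimum spacing
of the cohort (`compute_min_spacing`), trilinearly for intensities and
nearest-neighbor for the mask so it stays binary. The output grid covers
the input physical extent; a target too coarse to leave at least 2
voxels per axis is rejected.

**Discretization.** Texture, histogram and intensity–volume-histogram
families operate on gray levels discretized into a fixed number of
equal-width bins over the in-mask range (default `n_levels = 32`, the
common compromise between matrix sparsity and intensity resolution; a
fixed bin *width* is not offered because the synthetic intensities are
not calibrated HU). The maximum intensity maps to the top level; a
constant region maps entirely to level 1.

**The 102-feature manifest.** The descriptor set is fixed in
`manifest.py` (version 1.0) with per-family counts intensity 14,
histogram 14, volumetric/IVH 16, morphology 11, GLRLM 16, GLSZM 16,
NGTDM 5, LBP 10 — 102 total. Definitions follow IBSI conventions:

- *GLRLM*: runs accumulated over the 13 unique 3D directions, matrices
  summed ("merged") before features, so features are deterministic and
  direction-order free. Run percentage divides by voxels × directions.
- *GLSZM / NGTDM*: 26-connectivity (Chebyshev distance 1). NGTDM
  coarseness for a perfectly homogeneous region (all s_i = 0) returns a
  documented cap of 10^6 rather than infinity, preserving ordering.
- *Morphology*: volume by voxel counting (reported in cm³); surface
  area from a triangulated marching-cubes iso-surface at level 0.5
  (voxel-face counting systematically overestimates area and biases
  sphericity down); elongation/flatness from the eigenvalues of the
  voxel-center covariance; maximum 3D diameter over convex-hull
  vertices. Single-voxel masks use diameter 0 and elongation/flatness 1
  by convention.
- *LBP*: the operator is 2D by construction (a 3×3 block around each
  center), so it is applied per axial slice with P = 8, R = 1 and the
  rotation-invariant uniform mapping (10 codes); only centers whose full
  3×3 neighborhood is in-mask contribute, per-slice histograms are
  normalized and averaged over contributing slices.
- *IVH*: gray levels map to intensity fractions in [0, 1]; V(γ) is the
  volume fraction at intensity fraction ≥ γ and I_x the smallest
  achieved fraction with V ≤ x%. A constant region is defined as sitting
  at its (degenerate) maximum: V = 1 at every threshold.
- Moments use the population convention; skewness/kurtosis of a
  constant region are 0.

All features are invariant to whole-voxel translation; texture matrices
are verified exactly against brute-force enumeration (line walks, flood
fill, per-voxel neighborhood means) on randomized small grids.

## ComBat and nested harmonization

ComBat models feature g of sample j in batch level i as
`y = α_g + x'β_g + γ_ig + δ_ig ε`. The implementation standardizes by a
least-squares fit containing batch indicators and the protected
covariate design, estimates per-level location/scale (γ̂, δ̂²) on the
standardized scale, shrinks them by parametric empirical Bayes (normal
prior on location, inverse-gamma on scale, moment-matched
hyperparameters, fixed-point iteration to 1e-4 with a 100-iteration
cap), and returns `σ̂/δ* · (z − γ*) + α̂ + x'β̂`. Zero-variance features
cannot be standardized and are rejected (the nested driver removes them
with a warning first). The nonparametric EB variant is not implemented;
the parametric form is what radiomics applications of ComBat almost
always use.

**Protected covariates** enter the design so their variation survives
harmonization: categorical variables reference-coded, continuous
standardized, with a rank check that refuses designs confounded with the
batch variable. The default protected list includes the outcome (event,
PFS time) because the published procedure protects them; note this lets
outcome information shape the harmonized features and is therefore a
potential information leak into any later survival analysis — the list
is a plain argument and can be overridden.

**Nested ComBat** evaluates every ordering of the batch variables,
harmonizing sequentially from the original data, scores each fully
harmonized set by the total count of AD-significant features summed over
all batch variables, and keeps the minimizer; ties keep the ordering
closest to the supplied batch list, making the procedure deterministic.
The sum (rather than max) over variables is used as the score and the
per-variable counts are reported alongside. The k-sample
Anderson–Darling test uses the Scholz–Stephens asymptotic p-value, with
a seeded 2000-resample permutation fallback when any level has fewer
than 5 samples. Features with AD p < α for any batch variable after
harmonization are discarded as non-robust; α = 0 disables the filter.

**Recovery convention.** Planted batch shifts in the generator are
specified in units of the true per-feature SD, while ComBat estimates γ
in pooled-standardized units whose σ̂ is inflated by the planted scale
factor. Recovery checks therefore compare the between-level contrast of
γ* rescaled by σ̂/σ_true with the planted value; at n = 500 the mean
absolute error is below 0.1.

## Phenotype discovery

Features are z-scored per column before clustering — without this,
high-variance radiomic features dominate the Euclidean metric. Ward
clustering uses the squared-Euclidean merge-cost criterion (the modern
"Ward.D2"-style convention) via `scipy.cluster.hierarchy`; it is checked
against an exhaustive greedy merge oracle at small n.

**Consensus clustering** (defaults: 1000 resamples, 80% subsampling,
k ∈ 2..6) accumulates pairwise co-clustering over co-sampling counts and
summarizes stability per k as the area under the empirical CDF of the
upper-triangular consensus values; never-co-sampled pairs are excluded
and logged. Candidate k's are screened by the relative increase in CDF
area (threshold 0.1, configurable — the literature offers no canonical
value).

**SigClust** compares the observed two-cluster index
CI = within-cluster SS / total SS with its distribution under a
zero-mean Gaussian whose covariance eigenvalues are estimated from the
data and floored at a background-noise variance (pooled MAD of the
column-centered entries, scaled to Gaussian SD). Eigenvalues come from a
Ledoit–Wolf shrunk covariance: raw sample eigenvalues at moderate n/d
overstate anisotropy (the simulated null then looks more clusterable
than the data), which made the test reject at ~0.3% instead of 5% under
a spherical null; shrinkage restores calibration (measured type-I error
≈ 0.05–0.06 at n = 50, d = 10) while leaving power at large separations
intact. The default of 10,000 null simulations matches standard
practice; the cluster index on each null draw uses an in-package
vectorized 2-means (Lloyd, 10 seeded restarts), which is the standard
SigClust choice and orders of magnitude cheaper than running Ward per
draw. An unfloored variant is available via `floor_eigenvalues=False`.

**k selection** returns the largest k whose relative consensus-area gain
exceeds the threshold *and* whose every binary split up to k is
SigClust-significant at α = 0.05 (the split tested at each k is the
parent cluster that divides between the k−1 and k cuts); when nothing
qualifies it falls back to k = 2 with a logged "no significant
structure" flag.

## Survival association

Cox models use lifelines with Efron tie handling. Cross-validated
concordance follows the repeated-k-fold protocol: per iteration,
shuffle, split into 5 folds, fit on 4, score the held-out fold, pool the
out-of-fold risk scores into a single Harrell concordance — one value
per iteration, summarized by the mean and the 2.5/97.5 percentile
interval over (default) 200 iterations. Fold fits drop columns constant
within the fold and carry a light ridge penalty (0.01, escalated on
convergence failure) to stabilize sparse categorical levels; the
full-data fit used for risk scores is unpenalized. Kaplan–Meier curves
split the cohort at the median risk score (ties to the low group; if
ties swallow the cohort the split falls back to strictly-below) and are
compared by the 1-df log-rank test. Therapy-line stratification reruns
the identical procedure per stratum, skipping strata under 20 samples.

Clinical covariates are encoded per the standard categories: PD-L1
<10 / 10–50 / ≥50%, BMI underweight/normal/overweight/obese, smoking
former/current/never, ECOG 0–3, reference level first. PFS is carried
in days internally (months = days/30.44 where reported). Tumor volume
enters models as log volume. The PD-L1 random-forest probe binarizes
expression at ≥50% (configurable), uses a stratified 70:30 split and
reports both the five-fold CV AUC on the training part and the holdout
AUC.

## Synthetic cohorts

`simulate_feature_cohort` draws features as
`y = μ_g + m_cg σ_g + Σ β_v x_v σ_g + γ_ig σ_g + δ_ig σ_g ε` with
per-feature scales σ_g log-uniform in [0.5, 2] (so harmonization is
exercised on unequal scales), batch assignments independent of cluster
by default (a confounding knob forces a fraction of first-batch levels
to follow the cluster for stress tests), and multiplicative combination
of scale factors across batch variables. Planted cluster separation is
defined as the minimum pairwise centroid distance *after* per-feature
z-scoring — the scale clustering operates on; because standardization
caps the achievable distance at a finite asymptote (~2√d for two equal
clusters), unattainable requests raise an error rather than silently
under-separating. PFS times are exponential with hazard
`rate · exp(linear predictor)` and independent uniform censoring — the
simplest mechanism satisfying the non-informative censoring assumed by
the log-rank test and Cox model.

The default spec mirrors the motivating study design: 107 samples, 102
features, contrast 80/27 and kernel 90/17 level frequencies, planted
batch effects γ = 1.5, δ = 2 (no per-feature batch effect sizes are
published for such cohorts; these are deliberately strong so failure to
harmonize is visible), clinically realistic covariate distributions, baseline
PFS median 270 days, phenotype log-HR 0.4, censoring window 1460 days.
Tumor volumes are textured ellipsoids (mask = discretized ellipsoid,
intensities = class mean + Gaussian-correlated noise inside, lung-like
background outside); they exercise extraction but contain no CT physics
(no beam hardening, no kernel-dependent point-spread, no anatomy).

**What passing tests show — and don't.** The synthetic generator matches
the *statistical form* the methods assume (additive location/scale batch
effects, Gaussian within-cluster scatter, proportional hazards,
non-informative censoring). Real radiomic batch effects are not purely
location/scale, real phenotypes are not spherical Gaussians, and real
censoring is rarely uniform; green tests demonstrate correctness of the
implementations and recoverability under the assumed model, not
performance on any clinical cohort.

## Problem sizes and numerical choices

Unit and acceptance tests run the generator at the sizes stated in each
test (typically n = 100–500 samples, 10–102 features); the acceptance
script uses 500 consensus resamples, 2,000 SigClust null simulations and
the full 200 CV iterations on the 107-sample cohort — sizes chosen so a
complete from-scratch run stays within a few minutes on one CPU while
keeping Monte-Carlo error well below the decision thresholds. ComBat
iterates to 1e-4; consensus CDFs use a 101-point grid; all randomness
flows through explicit integer seeds (the pipeline fans one global seed
out to fixed per-stage offsets).

## Known limitations

- The exact composition of the 102-feature set is a versioned in-package
  convention (IBSI-faithful); other radiomics platforms will not emit
  numerically identical features.
- DICOM series, multi-lesion aggregation, longitudinal/GAM ComBat and
  site imputation for unseen levels are out of scope.
- Protecting outcome variables during harmonization follows the
  published procedure but couples features to outcome; use a reduced
  protected list when unbiased downstream inference matters.
- SigClust calibration was verified at the tested sizes (n ≈ 50–100,
  d ≈ 10–100); heavy-tailed data can still make the Gaussian null
  anti-conservative.
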