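# Methods

This note records the modelling conventions, defaults and numerical
choices of `radsurv`, and what the synthetic test bed does and does not
establish about behaviour on real CT data.

## Geometry and preprocessing

Voxel arrays are ordered `(x, y, z)` with `z` the slice axis; coordinates
refer to voxel centers, 0-based; spacing is in millimetres. All cases of a
study are resampled to the per-axis **minimum spacing** of the dataset
(config `target_spacing: auto-min`, or an explicit triple) with trilinear
interpolation on a grid that spans the same physical extent. Masks are
interpolated as real-valued fields and thresholded at 0.5; grid points
landing exactly on the half-level surface take the floor-voxel value — a
uniform strict (or inclusive) rule would erode (or dilate) the entire tie
shell and bias the mask volume by the half-voxel surface layer, which is
visible when only one axis is refined by an integer factor.

Dual-rater masks are merged by voxelwise **union** when their discrepancy
— symmetric difference over union, `|A⊕B|/|A∪B|` (1 − Jaccard) — is below
0.05; otherwise an adjudicated mask must be supplied. The union rule
follows the convention that the ROI covers the whole tumor; the
discrepancy metric was chosen because it is symmetric, bounded in [0, 1]
and zero iff the masks agree. Whether the original 5 % rule referred to
volume difference or voxelwise overlap is not decidable from the source
description; the overlap form is the stricter and is used throughout.

## Wavelet filtering

The 8 wavelet images are the subbands of a **single-level stationary
(undecimated) separable 3-D Coiflet-1 transform**: convolution along x,
then y, then z with the 6-tap low-pass (L) or high-pass (H) filter — the
first subband letter names the x-axis filter, the last the z-axis.
Undecimated filtering keeps every subband on the input grid, so the tumor
mask applies unchanged when intensity and texture features are recomputed
per subband (a decimated transform would require resampling the mask and
would halve the ROI per axis). Boundary handling is symmetric (mirror)
extension, which avoids the edge ramps zero-padding would create inside
small tumors. The high-pass filter is derived from the low-pass taps by
the quadrature-mirror relation `g[k] = (−1)^k h[N−1−k]`.

`iswt3` inverts the transform by solving, per axis, the least-squares
normal equations of the analysis operator (including the symmetric
extension). The common "convolve with time-reversed filters and average"
synthesis is exact only in the interior for the asymmetric Coiflet taps;
the least-squares inverse is exact everywhere (reconstruction error
~1e-12, well inside the 1e-8 tolerance asserted in tests). The per-length
operator matrices are cached; the Gram matrix is ≈ 2·I away from the
boundary and is well conditioned.

## Feature panel (620 features)

Counts per family: histogram 17, shape 8, GLCM 22, GLSZM 13, GLRLM 11,
NGTDM 5. The original image contributes all 76; each of the 8 subbands
contributes the 68 intensity/texture features (shape is mask-only and
appears once), 76 + 8 × 68 = 620. Names follow
`{Original|Coiflet_<subband>}__{family}__{feature}` in a fixed order.

**Discretization.** Texture families operate on 32 equal-width bins
spanning the min–max of the masked intensities, computed separately for
the original image and each subband. A constant region degenerates to a
single level. 32 bins is the common radiomics default and bounds matrix
sizes; the bin count is a parameter of every feature function.

**First-order.** Population moments (variance, skewness, kurtosis;
kurtosis non-excess so a normal sample gives ≈ 3). Entropy/uniformity use
the 32-bin histogram with log₂ and 0·log 0 = 0. The "standard" entropy
and uniformity variants z-score the intensities first and bin them on a
fixed [−4, 4] grid (clipped): unlike min–max binning, which is affine
invariant, the standard variants therefore measure distribution shape on
a standardized scale. `Mass` is the summed intensity of the region.
Degenerate (constant) regions: variance/skewness/kurtosis/entropies 0,
uniformity 1.

**Shape.** Volume = voxel count × voxel volume. Surface area = summed
area of exposed voxel faces: deterministic and exactly checkable against
closed forms (single voxel 6 mm², 2×2×2 cube 24 mm²), at the cost that a
digitized smooth surface is overestimated by a factor approaching 1.5, so
the sphericity of digitized balls converges to 2/3 rather than 1 — values
are comparable within this convention, not with mesh-based toolkits.
Maximum 3-D diameter is the largest pairwise distance between
boundary-voxel centers (convex-hull pruning above 400 boundary voxels).

**Texture.** GLCM: distance-1 offsets over the 13 unique 3-D directions,
symmetric accumulation, probability normalization; features computed per
direction and averaged. Correlation of a degenerate (σ = 0) matrix is
defined as 1; information measures guard their logs and denominators with
ε = 1e-12. Sum variance is centered on the sum average. GLSZM: zones are
26-connected components of equal level, one direction-free matrix.
GLRLM: maximal runs along the 13 directions, features averaged. NGTDM:
neighborhoods are the 26-connected masked voxels; voxels with no masked
neighbor are excluded; constant regions give contrast 0 and coarseness at
the 1/ε sentinel (1e12). All denominators carry ε = 1e-12; any
non-finite feature value is clamped to 0 with a logged warning.

## Radiomic signature (LASSO-Cox)

Features are standardized (zero mean, unit variance) before penalization;
constant columns are dropped with a warning. The L1 path is solved by the
glmnet-style coordinate descent of scikit-survival's Coxnet with Breslow
tie handling; the default grid is 100 log-spaced values from the all-zero
entry point λ_max down to 0.01·λ_max. λ is selected as the minimizer of
the **leave-one-out cross-validated partial-likelihood deviance** using
the Verweij–van Houwelingen linear-predictor construction:
`CV_i(λ) = ℓ(full data; β₋ᵢ) − ℓ(data without i; β₋ᵢ)`, deviance
−2 Σᵢ CV_i. λ_min is used (not a 1-SE rule), matching "smallest
cross-validation error". Coefficients are reported on the original
feature scale (β_orig = β_std / sd); the per-patient signature is
Σⱼ βⱼ xⱼ over the non-zero set, so standardized and original-scale fits
agree up to one constant shift that cancels in every downstream rank- or
threshold-based use (the threshold is computed on the same scale).

Risk groups: signature > training-cohort median → high risk; ties go to
low risk. The median is always computed on the training cohort only.

## Survival validation

Kaplan–Meier estimation and the two-group log-rank test come from
lifelines. Harrell's C uses the risk-score convention (higher marker,
earlier event), ties counted 0.5, with percentile-bootstrap 95 % CIs over
patients (B = 1000; bootstrap draws without events are skipped).

**Time-dependent ROC (NNE).** Cumulative cases (event by t), dynamic
controls (event-free at t). The bivariate survival function
S(c, t) = P(X > c, T > t) is estimated as the average over patients of a
nearest-neighbor weighted Kaplan–Meier: the neighborhood of patient i is
the fraction `span` of patients nearest in marker **rank** (box kernel),
making the estimator invariant under strictly monotone marker transforms.
Default span 0.25·n^(−0.20), exposed as a parameter. Sensitivity and
specificity follow from S(c, t) and the marker CDF; AUC by trapezoid over
thresholds midway between observed marker values. The 3-year horizon is
36 months.

**DeLong.** DeLong's test is defined for binary outcomes; at a survival
horizon t the comparison uses patients evaluable at t — events by t are
cases, patients followed beyond t are controls, patients censored before
t are excluded. Identical markers (zero variance of the AUC difference
with equal AUCs) return p = 1 by convention.

**Calibration.** Patients sorted by predicted event probability are split
into at most 10 bins of ≥ 10; observed event probability per bin is
1 − KM(t) within the bin (handles censoring; raw proportions would be
biased by censoring before t). Hosmer–Lemeshow chi-square with g − 2 df.

**Nomogram.** Points for covariate j at value x:
`100·βⱼ·(x − refⱼ)/max_k |β_k|·range_k`, with refⱼ the
minimum-contribution end of the covariate's range, so the dominant
covariate spans exactly 0–100 and all points are non-negative. Total
points map back to the linear predictor and through the Breslow baseline
(S₀ at x = 0, uncentered — equivalent to the mean-centered form) to
survival probabilities at 18 and 36 months. The round trip
nomogram → points → probability agrees with the direct Cox prediction to
numerical precision. Wald standard errors come from the observed Breslow
information matrix.

## Cohort statistics

Two-sided Fisher exact p-values use the probability-mass convention (sum
of probabilities of margin-consistent tables no more probable than the
observed, 1e-7 relative slack) — the convention that reproduces the
published three-decimal table values; the r×c generalisation
(Freeman–Halton) enumerates all margin-consistent tables and is bounded
to totals ≤ 500. Group means: pooled-variance t-test for two groups
(Welch via `equal_var=False`), one-way ANOVA for three or more. Rater
agreement: ICC(2,1) — two-way random effects, absolute agreement, single
rater — computed from the ANOVA mean squares.

## Synthetic data: what it emulates, and what it does not

**Phantoms.** An ellipsoidal tumor (mean 40 HU, texture SD 20 HU) on a
−50 HU background with 2 HU additive noise, default 16³ voxels at 1 mm.
The interior is a Gaussian random field whose correlation length is set
by the texture class (smooth σ = 2.5 voxels, rough σ = 0.6): a shorter
correlation length provably increases co-occurrence contrast, giving a
testable link from construction to feature behaviour. Rater masks are the
true mask with independent random boundary flips, the flip count
calibrated so the pair discrepancy lands within ±0.01 of the target
(default 0.03). Everything is a pure function of spec + seed.

**Cohorts.** Features are exchangeably correlated normals (default
ρ = 0.2); event times follow a Weibull proportional-hazards model
S(t|x) = exp(−(t/scale)^shape·e^{xβ}) with shape 1.5 and scale chosen so
the median event time at x·β = 0 is 18 months (the commonly quoted median
PFS in the target disease — a scenario default, not a claim); censoring
is administrative, uniform over 18.8–81.8 months, emulating a study
window with a minimum 18-month follow-up. Clinical covariates are drawn
at the published pooled marginals (FIGO IV 21 %, postoperative
CA-125 > 35 U/mL 46 %, residual > 0 cm 58 %, bilateral 50 %,
premenopausal 29 %) with age and preoperative CA-125 log-normal around
the published medians/IQRs (50 years, 713.6 U/mL).

Passing tests on this bed establish that the machinery is correct
(matrices match brute-force oracles, estimators recover known parameters,
null tests are calibrated, the pipeline is deterministic). They do not
establish that the selected features or effect sizes transfer to real CT:
phantoms have no scanner noise spectra, beam hardening, HU calibration
drift, anatomy, or inter-scanner variation, and the simulated feature
correlation structure is far simpler than a real radiomics panel's.

## Problem sizes in the shipped checks

The test suite and the acceptance script exercise: LASSO recovery at
n = 200 with 50 features over 20 seeds (exponential baseline, ~30 %
censoring); Cox recovery at n = 500 with independent covariates (the
recovery bound concerns estimator bias/variance, not collinearity);
DeLong and Hosmer–Lemeshow null calibration over 200 replicates; null
concordance at n = 1000; and an end-to-end 30-case (16³) pipeline run
executed twice for byte-identity. These sizes keep the whole suite within
a few minutes on a single CPU while leaving the statistical assertions
well-powered.

## Known limitations

* Texture conventions (bin count, GLCM distance set, the "standard"
  first-order variants) follow the dominant radiomics lineage but are
  conventions; published coefficient values are only transferable between
  implementations that share them exactly.
* The face-count surface area (and features derived from it) is biased
  upward for smooth shapes, as discussed above.
* The Freeman–Halton enumeration is exponential in table size and
  deliberately bounded; a Monte-Carlo fallback is suggested by the error
  message but not implemented.
* DICOM series reading takes spacing from the series header; no HU
  recalibration or scanner harmonisation is attempted beyond resampling.
* The LOOCV criterion refits the penalty path once per left-out patient;
  for n beyond a few hundred a k-fold criterion would be the practical
  choice (not implemented, as the target cohorts are small).
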