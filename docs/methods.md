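# Methods

This note records the statistical model behind `polyvoxel`, the choices
made where the design was genuinely open, what the synthetic generator
does and does not emulate, and the package's numerical conventions.

## 1. The PolyVoxel Score

### Preprocessing

Each masked voxel column is mapped through its ranks to standard-normal
quantiles, Φ⁻¹((rank − 3/8)/(n + 1/4)), with average ranks for ties (the
Blom offset; recorded in the `TransformSpec` so the convention is
reproducible).  Columns are then replaced by their least-squares residual
on a covariate design of intercept, age, sex, scanner one-hot (reference
level dropped) and the top 10 genetic PCs.  The order is
transform-then-residualize, so residuals are exactly orthogonal to the
design.

Out-of-sample data reuse the *training* state: test values are mapped by
linear interpolation between the sorted training values and their normal
images, clamped to the boundary quantiles outside the training range, and
residualized with the training coefficients applied to the test subjects'
own covariates.  No statistic is re-estimated on test data.  Applying a
spec to its own training matrix reproduces the training output exactly.

### Estimator

With preprocessed training matrix **X** and case indicator **y**:

* **z** holds the per-voxel simple-regression slope z (the Pearson t
  mapped through its two-sided p to a normal deviate);
* voxels are retained where two-sided *P* < 0.01 (|z| > 2.5758 at the
  default threshold);
* **R** is the correlation matrix of the *retained* training columns.
  (Computing **R** over all voxels is both infeasible at scale and
  irrelevant — weights exist only for retained voxels.  This choice is
  pinned by tests.)
* the symmetric eigendecomposition **R** = **U S U**ᵀ serves as its SVD;
  tiny negative eigenvalues (numerical) are clamped to 0 first;
* **S**ᵣ keeps the *r* largest eigenvalues and floors the remainder at
  the *r*-th largest; weights are **w**ᵣ = **U S**ᵣ⁻¹ **U**ᵀ **z**; the
  PVS is **w**ᵣᵀ**x**.

If the *r*-th eigenvalue is exactly zero (possible at *r* = M when the
retained-voxel count exceeds the sample size), the floor is raised to
max-eigenvalue × 10⁻¹² so the inverse stays defined; this mimics a
pseudo-inverse and only arises in the deliberately unregularized grid arm.

**Orientation.**  The score is oriented so that a *higher* PVS means
"more archetype-like": if the mean training case score falls below the
mean control score, the weights are negated (recorded in model metadata).
Because the archetype darkens T2-weighted intensity, correctly oriented
weights are *negative* where the archetype pattern loads — pattern
recovery is therefore measured against the expected voxel effect of the
genotype on the modality (−pattern), not the raw pattern.

### Rank selection

Stratified 5-fold cross-validation over the grid
[1, 5, 10, 20, 50, 100, 200, 500, 1000, M].  Everything — preprocessing,
z-map, threshold, **R**, weights — is refitted inside each training fold.
AUC is the selection metric (the estimator's association measure for a
binary target; recorded in `CVResult`).  Exact AUC ties break to the
smallest r (strongest regularization, determinism).  The selected rank is
the rounded mean of the per-fold optima and may fall off-grid (e.g. 13
from a grid without 13); callers may override it.

### Matched training cohort

Cases are archetype homozygotes with imaging; controls are imaged
wildtypes (heterozygotes are excluded from both sides).  Matching is 4
controls per case, exact on sex and scanner, greedy nearest-neighbour on
standardized (age, PC1..PC10) Euclidean distance, without replacement, in
a seeded random case order.  Greedy nearest-neighbour is a documented
choice — standard, deterministic, and verifiable against exhaustive
search at small n; any stratum that cannot supply the full complement
raises an error naming the stratum (never a silent shortfall).
Subsample B is every imaged subject outside A who is not homozygous;
subsample C (used by the quantile risk analysis) is B plus *all*
homozygotes and is exposed as a derived mask since it is a superset of B.

## 2. Iron estimation

T2\* values are stored in **milliseconds** throughout; the rate conversion
is R2\* [Hz] = 1000 / T2\* [ms].  Concentration uses the liver-calibrated
relationship iron [µg/g dry] = C · R2\*/3.2 with C = 2000/36, applied
exactly.  Per-subject summaries average R2\* over the fitted model's
retained voxels.  Known limitations of the calibration (two-echo
acquisition, liver-tissue constants, no bivalent/trivalent distinction)
are properties of the published formula and are not modelled.

## 3. Risk models

Imaging subsamples under-represent cases, so imaged cases are weighted by
the full-to-imaging prevalence ratio (IPW); all other observations weigh
1.  Weighted logistic fits maximize the weight-multiplied log-likelihood
(IRLS via a GLM with frequency weights); Wald intervals come from the
weighted information matrix.  A sandwich (robust) option exists behind a
flag — IPW analyses often warrant it — but the model-based default
mirrors the simplest reading of a weighted regression.  The continuous
PVS is standardized before entry so its OR is per SD (recorded in fit
metadata).

The quantile analysis assigns each scored, non-homozygous subject to a
PVS quartile (boundaries from the sample quartiles of that group; ties to
the lower quartile), with homozygotes as their own category and the 4th
quartile as the reference level — homozygotes are excluded from boundary
estimation because they are absent from the scoring subsample by
construction.  The reference term never appears in the output.

## 4. Replication analytics

Per-variant OLS of the score on dosage plus covariates (monomorphic
variants are flagged, not tested).  Sign concordance counts strictly
equal nonzero signs (a zero estimate is discordant) and is tested with an
exact two-sided binomial at null probability ½ implemented by *doubling
the smaller tail* and capping at 1 — the doubling rule reproduces the
canonical 12-of-13 → p = 0.003418.  Effect-size correlation is Pearson's
r over the selected betas.  Variant selection at this scale is by
p-threshold only; linkage-disequilibrium pruning is out of scope because
the generator plants no realistic LD.

## 5. The synthetic generator

The generator emulates the statistical skeleton the analysis relies on,
not MRI physics:

* **Latent iron** L = γ·1[homozygote] + covariate effects + optional
  planted-variant effects + N(0, σ²).  Covariates (age, sex, scanner, 10
  PCs) act on both L and intensities, creating the confounding that
  residualization must remove.
* **T2w**: x = −pattern·L + confound + σ·ε with AR(1) voxel noise,
  corr(ε_v, ε_w) = ρ_s^|v−w|.  The 1-D AR(1) ordering stands in for real
  3-D spatial covariance: it preserves the correlated-voxel structure
  that makes the regularized inverse matter, at desk scale.
* **T2\***: R2\* = base + slope·pattern·L + noise (affine increasing in L
  over pattern voxels, so ground-truth concentration is recoverable
  through the calibration formula), stored as T2\* in ms.
* **Outcome**: logit P = β₀ + β₂(L − L_opt)², i.e. risk is quadratic in
  the distance from an optimal iron level — the hormetic mechanism.
* **Imaging flag**: drawn so the imaging subsample's expected case
  prevalence is the full prevalence divided by the configured depletion
  factor (P(imaging|case) = q₀(1−p)/(d−p)).

All draws flow from one seed through per-stage child streams; identical
configurations are bit-identical.

What it does **not** emulate: anatomy, registration error, scanner
harmonization artifacts, realistic LD, longitudinal structure.  Passing
tests therefore demonstrate that the *estimators* behave as designed
under the assumed data-generating process, not that the pipeline is
robust to real-world acquisition artifacts.

### Named study conditions

* `recovery_config` — n = 1200 subjects, 600 voxels with a 120-voxel
  pattern, ρ_s = 0.5, γ = 2.5, σ = 1, homozygote rate 0.12.  γ = 2.5 makes
  the best achievable case/control AUC ≈ Φ(γ/(σ√2)) ≈ 0.96 — a strong but
  not degenerate signal.  The enriched homozygote rate mirrors training on
  an enriched case-control subsample (the population rate is ~1/200) and
  leaves every sex × scanner stratum enough wildtype controls for 4:1
  matching.
* `null_config` — γ = 0, β₂ = 0, n = 2000 with a 20% case rate, M = 2000
  spatially *independent* voxels (ρ_s = 0, no image confound loadings, one
  token pattern voxel).  Independence is deliberate: the Binomial(M, 0.01)
  reference for the retained-voxel count only applies to independent
  tests — shared latent factors over-disperse the count.  The sample size
  keeps the chance-AUC sampling error near 0.016, small against the
  [0.44, 0.56] calibration band.  Measured over 40 000 null voxels the
  retention rate is ≈ 0.0095: the normal-theory p of a simple-regression
  slope on a binary outcome is very mildly conservative, a property of
  the method as published.
* `hormesis_config` — n = 12 000, β₀ = −3, β₂ = 0.3, L_opt = 1.5, γ = 3,
  homozygote rate 0.01, imaging depletion 3.89.  The population mean of L
  (~0) sits on the low-iron limb of the risk curve while homozygotes
  (L ≈ 3) sit on the high limb, producing the characteristic U: elevated
  odds in the lowest score quartile *and* in homozygotes relative to the
  top quartile.  The depletion factor matches the motivating
  movement-disorder IPW.
* `replication_config` — 40 background variants, 8 causal with effect SD
  0.4 on L, for the discovery/replication analytics.

Problem sizes throughout (hundreds to thousands of subjects, hundreds to
thousands of voxels) are chosen as the smallest scales at which the
recovery properties are statistically stable; they are the package's
stated desk-scale study conditions.

## 6. Numerical conventions and degenerate inputs

* Masked voxel order is the C-order scan of the mask volume, everywhere.
* Constant voxel columns cannot be rank-transformed and raise an error;
  constant columns in a z-map contribute z = 0.
* Two-sided p-values are floored at 10⁻³⁰⁰ before the normal-quantile
  map, bounding |z| ≈ 37.
* Correlation-matrix inputs must be symmetric with unit diagonal (10⁻⁸
  tolerance); violations raise rather than being silently repaired.
* Residual orthogonality to the design holds to |corr| < 10⁻⁸ on
  training data (test-pinned).
* Separation or non-convergence in weighted logistic fits raises; results
  with non-finite or exploding coefficients are never returned.
* Empty risk categories, empty variant selections, and empty retained-
  voxel sets are errors, not warnings; empty atlas regions and empty
  grouping levels are skipped with a warning.

## 7. Known limitations

* The 1-D AR(1) spatial model understates the long-range correlation of
  real volumetric data; cross-validated ranks here are therefore small
  (often 1–5), whereas richer covariance structure favours larger ranks.
* Wald intervals with frequency weights treat weights as replication
  counts; for strongly depleted outcomes the robust (sandwich) option is
  the safer inference.
* The iron calibration constant is taken as exact; no uncertainty is
  propagated through the concentration estimates.
* The quantile analysis assigns homozygotes a placeholder score (they
  form their own category and never touch quartile boundaries), so their
  OR is interpretable only as a category contrast, not on the PVS scale.
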