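# polyvoxel

Voxel-level archetype scoring for brain-iron dysregulation, with the full
downstream analysis chain: matched-cohort classifier training, regularized
decorrelation of mass-univariate statistics, out-of-sample scoring, region
importance, R2\*-based iron-concentration estimation, inverse-probability-
weighted disease-risk models (including a quantile U-shape analysis), and
discovery/replication concordance statistics.  A synthetic-data generator
with retained ground truth makes every stage testable end to end without
access-controlled cohort data.

## The problem

Homozygosity for the most common hereditary-hemochromatosis variant causes
excessive dietary iron absorption and a stereotyped pattern of iron
accumulation in motor circuits, visible as darkening of T2-weighted MRI.
Treating that genotype as an *archetype* of brain-iron overload, one can
train a classifier to recognize the pattern and then score unaffected
subjects along the same axis.  The resulting per-subject **PolyVoxel Score
(PVS)** behaves as a quantitative endophenotype of central iron
dysregulation: it is usable as a GWAS phenotype, and its relationship to
movement-disorder risk is *hormetic* — risk rises at both the iron-deplete
and iron-overload ends.

## The model

Let **X**<sup>train</sup> be the masked subjects × voxels intensity matrix,
each column rank-inverse-normal transformed and residualized on age, sex,
scanner and 10 genetic PCs, and **y**<sup>train</sup> the case indicator.

1. Mass-univariate association gives a z-vector **z** (simple-regression
   slope z per voxel); voxels are kept where two-sided *P* < 0.01.
2. The correlation matrix **R** of the retained training columns is
   eigendecomposed, **R** = **U S U**ᵀ, and regularized by keeping the *r*
   largest eigenvalues and replacing the rest with the *r*-th largest
   (**S**<sub>r</sub>).
3. Posterior (decorrelated) weights are **w**<sub>r</sub> =
   **R**<sub>r</sub>⁻¹ **z** with **R**<sub>r</sub> = **U S**<sub>r</sub>
   **U**ᵀ, and a subject's score is ŷ = **w**<sub>r</sub>ᵀ **x**.
4. The rank *r* is chosen by stratified 5-fold cross-validation over the
   grid [1, 5, 10, 20, 50, 100, 200, 500, 1000, M], maximizing held-out
   AUC; the selected value is the rounded mean of per-fold optima (so it
   may fall off-grid).

Downstream: per-region importance is the share of the squared unit-
normalized weight map; iron concentration uses the published calibration
iron [µg/g dry] = (2000/36) · R2\*[Hz] / 3.2 with R2\* = 1/T2\* averaged
over retained voxels; disease models weight imaged cases by the
full-to-imaging prevalence ratio (IPW); and sign concordance between
discovery and replication effect estimates is tested with an exact
two-sided binomial test at null probability ½.

## Worked example

```sh
python examples/02_fit_and_score.py
```

prints (seed 0):

```
training set A: 163 cases, 652 matched controls
  r =    1: mean held-out AUC 0.956
  r =    5: mean held-out AUC 0.953
  ...
  r =    M: mean held-out AUC 0.901
fold-optimal ranks [1, 1, 1, 5, 1] -> selected r = 2

fitted model: 133 voxels at P < 0.01
held-out subsample B (n=385): corr(PVS, true latent iron) = 0.877
```

Small ranks beat the unregularized *r* = M because the AR(1)-correlated
voxel noise makes the raw inverse of **R** unstable — exactly the regime
the truncated-eigenvalue regularization is built for.  The held-out
correlation of 0.877 says the score recovers the generator's latent iron
axis in subjects the model never saw.  `examples/05_risk_u_shape.py`
continues the chain and prints the U-shape: odds ratios versus the top
PVS quartile of 9.59 for the lowest quartile and 6.44 for archetype
homozygotes, with the middle quartiles near 1 — elevated risk at *both*
ends of the iron spectrum.

Other entry points: `examples/01_simulate_study.py` (generator anatomy),
`03_region_importance.py`, `04_iron_estimation.py`, `06_replication.py`,
and a thin CLI (`polyvoxel simulate | build-cohort | fit | score |
importance | iron | risk | replicate | run-all`) for file-based runs.

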