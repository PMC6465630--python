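# radsurv

CT-radiomics prognostic modelling for tumor recurrence risk.

`radsurv` implements, as a tested and reusable Python package, the classic
CT-radiomics survival workflow used to build recurrence-risk markers for
solid tumors (the motivating application is progression-free survival, PFS,
in advanced high-grade serous ovarian cancer):

1. **Feature panel.** From a CT volume and an aligned binary tumor mask —
   after resampling every case to the dataset's minimum voxel spacing and
   merging dual-rater masks under a 5 % disagreement rule — a fixed panel of
   **620 three-dimensional radiomic features** is extracted: 17 first-order
   (histogram) statistics, 8 shape features, and 51 texture features
   (22 GLCM + 13 GLSZM + 11 GLRLM + 5 NGTDM) on the original image, plus the
   17 + 51 intensity/texture features on each of the **8 subbands of a
   single-level stationary 3-D Coiflet-1 wavelet transform**
   (LLL, LLH, …, HHH), for 76 + 8 × 68 = 620 features (544 wavelet-derived).
2. **Radiomic signature.** An L1-penalized (LASSO) Cox regression of PFS on
   the standardized feature panel, with the penalty λ chosen by minimum
   leave-one-out cross-validated partial-likelihood deviance, reduces the
   panel to a handful of features. The *radiomic signature* of a patient is
   the linear combination Σⱼ βⱼ xⱼ over the selected features, reported on
   the original feature scale.
3. **Risk stratification and validation.** Patients are split into
   high-/low-risk groups at the training-cohort median signature;
   discrimination and calibration are assessed per cohort with
   Kaplan–Meier curves and the log-rank test, Harrell's C with
   percentile-bootstrap 95 % CIs (B = 1000), and time-dependent ROC curves
   at the 18-month and 3-year horizons built with the nearest-neighbor
   bivariate survival estimator (NNE).
4. **Nomogram.** A multivariable Breslow-tie Cox model combines the
   signature with seven clinical covariates (age, FIGO stage, pre-/
   post-operative CA-125, residual tumor, tumor side, menopause status) and
   is rendered as a points-based nomogram; model comparison uses DeLong's
   test and calibration the Hosmer–Lemeshow test over risk-sorted bins of
   ≥ 10 patients.

Because no patient imaging is distributed, the package ships a first-class
synthetic-data module: textured ellipsoidal phantoms (whose Gaussian-random-
field texture provably orders GLCM contrast), dual-rater mask perturbations
calibrated to a target disagreement, and Weibull proportional-hazards
cohorts with known coefficients and administrative censoring. Every stage
of the pipeline is exercised end-to-end on these generators.

## Worked example

Simulate a 30-case dataset (16³-voxel phantoms; rough-textured tumors carry
a hazard ratio of 3 over smooth ones), extract features, and run the full
analysis:

```bash
radsurv simulate --out demo --n-cases 30 --seed 7
radsurv extract  --config demo/config.yaml
radsurv analyze  --config demo/config.yaml
radsurv report   --in demo/results
```

which prints (numbers from this exact invocation):

```
signature: 3 features at lambda=0.4851
IVC: n=15 events=15 C=0.505 [0.281, 0.695] logrank p=0.1734
TC: n=15 events=14 C=0.808 [0.629, 0.945] logrank p=0.002955
```

Reading this: the LASSO-Cox fit on the 15 training-cohort (TC) phantoms
kept 3 of the 620 features at the LOOCV-optimal penalty; the TC median
split separates high- from low-risk phantoms (log-rank p ≈ 0.003) and the
signature's concordance in the TC is 0.81 (bootstrap 95 % CI 0.63–0.95).
At n = 15 per cohort the internal-validation (IVC) estimate is noisy —
exactly the small-sample behaviour the synthetic bed is meant to expose.
`demo/results/` also contains `features.csv` (30 × 620), `report.json`
(per-cohort C-indices, horizon AUCs, DeLong and Hosmer–Lemeshow results),
`signature.json` and `nomogram_points.csv`.

The same objects are available as a library, statsmodels-style:

```python
from radsurv.signature import RadiomicSignatureModel
from radsurv.synthetic import SimCohortSpec, simulate_cohort

cohort = simulate_cohort(SimCohortSpec(n=120, beta={"f000": 1.0}, n_features=15, seed=42))
result = RadiomicSignatureModel.from_cohort(cohort).fit()
print(result.summary())          # selected features + original-scale weights
scores = result.signature(cohort.features)
```

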