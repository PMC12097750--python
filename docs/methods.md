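# Methods

This note documents the statistical procedure the package implements,
the synthetic data it is validated on, the numerical conventions, and
the limits of what the test suite demonstrates.

## The selection procedure

For each outcome (PCQ total and its emotional/physical/social
subscales) the analysis sample is the set of rows complete on the
outcome **and all 24 candidate predictors** (complete-case analysis; no
imputation). The same row set is used for selection, refitting and the
outcome-SD reference, so every reported quantity refers to one sample.

**LASSO core.** Predictors are standardized to mean 0, population SD 1;
the response is centered. The objective is

    (1/(2n))·‖y − Xβ‖² + λ‖β‖₁,

the convention under which λ_max = max_j |x_jᵀy|/n is the smallest
penalty with an all-zero solution. Cyclic coordinate descent runs in
covariance-update (Gram) form, JIT-compiled with numba; convergence is
declared when the largest coefficient update in a sweep is below
`tol = 1e-7`. A pure-Python residual-update sweep that asserts the
objective never increases is kept as a debug path and cross-checked
against the compiled kernel in the tests. Coefficients are
back-transformed (β_raw = β_std/sd_j, intercept from the means) so all
reported effects are unstandardized.

**Penalty grid and cross-validation.** 100 log-spaced penalties from
λ_max down to 0.001·λ_max (defaults; both configurable). Folds are a
seeded shuffle into k = 10 blocks with sizes differing by at most one.
Within each fold the training split is standardized on its own and the
warm-started path fitted on the shared grid; validation MSE is computed
from back-transformed coefficients on the raw held-out block. λ_min is
the grid value minimizing mean validation MSE; ties go to the largest
penalty (the sparser model). The 1-SE rule is deliberately not the
default — the procedure documented here uses the minimal λ.

**Bootstrap stability selection.** B = 100 case resamples (rows drawn
with replacement, resample size n). Each resample gets a fresh fold
shuffle and a full CV-LASSO; a predictor counts as *relevant* in that
resample when its coefficient at λ_min is nonzero. Predictors with
selection frequency ≥ 0.80 (inclusive, "at least 80%") form the
selected set. A resample with a constant outcome is redrawn once, then
dropped with the frequency denominator reduced (logged).

**Final models.** The selected set is refitted with CV-LASSO on the
same B resamples (identical resampled rows, guaranteed by the seed
derivation below). Per-predictor raw coefficients are averaged over the
B refits; a refit in which the penalty zeroes a predictor contributes
that zero — shrinkage is part of the estimator being summarized. The
standard error is the across-bootstrap SD of the coefficients, and the
default 95% CI is mean ± 1.96·SE; this normal-approximation convention
is the one consistent with reporting coefficient/SE/CI triples such as
(2.72, 0.066, [2.59; 2.85]). Percentile intervals are available via
`ci_method="percentile"`. RMSE/MAE are computed on each bootstrap's own
fitting sample (in-sample) and averaged; the model is flagged *well
fitted on average* iff averaged RMSE < SD(outcome) in the original
sample. A CI endpoint exactly at 0 counts as covering 0 (not
significant). Report rounding: 2 decimals for coefficients, CIs and fit
metrics, 3 for SEs.

**Reproducibility.** Every random draw derives from one master seed via
`SeedSequence([master_seed, crc32(outcome), bootstrap_index, stream])`,
so runs are byte-identical under a fixed master seed, per-outcome
streams are independent of processing order, and the refit stage
reproduces the selection stage's resamples exactly.

**Group comparison.** Mann–Whitney U with midranks; exact null
distribution when n₁·n₂ ≤ 400 and the pooled sample is tie-free,
otherwise the tie-corrected normal approximation with continuity
correction, two-sided. Both U conventions (either group) are returned;
`compare_groups` reports the positively screened group's U.

## The synthetic survey generator

The generator stands in for the survey data in all tests. It emulates:

- **Predictor marginals.** Continuous predictors are clipped normals
  with the published means/SDs (age 62.37/12.26, subjective social
  status 7.00/1.70, communication-competence indices, health-literacy
  indices, comorbidity severity 1.73/1.26). Few-level ordinals are
  latent-normal thresholded onto published category percentages (e.g.
  social support 31.4/48.3/20.2% poor/moderate/strong); counts like
  household size round a latent normal. Binaries are thresholded
  latents (positive screen defaults to 4%). Category splits only
  summarized in the source tables (treatment-evaluation items,
  information satisfaction, education) were completed with plausible
  splits consistent with the published margins.
- **Collinearity.** One shared latent Gaussian factor with loading 0.3
  on every predictor's latent, giving mild positive pairwise
  correlation (~0.09) so the penalty's robustness to collinearity is
  exercised. The real survey's correlation matrix is unpublished; the
  loading is a free parameter, not an estimate.
- **Outcomes.** Each subscale is a censored rounded Gaussian latent:
  score = clip(round(intercept + signal + σ·e), 0, scale max), with the
  three subscale residuals sharing a common component (correlation
  0.738) and the total defined as the sum of the subscales, so the PCQ
  scoring identity holds by construction. Intercepts (0.527, 0.511,
  −0.677), residual SDs (6.805, 4.558, 3.490) and the shared-noise
  correlation were calibrated numerically (nested bisections at
  n = 300,000) so the generated subscales match the published moments
  (3.26/4.43, 2.27/3.08, 1.24/2.05) and the total SD matches 8.61. The
  generated total mean is ≈6.8 — the sum of the published subscale
  means — which the published table itself prints inconsistently as
  6.44.
- **Effect-size semantics.** Matching those moments forces roughly half
  of the latent mass below the floor, which would attenuate a latent
  slope by ~2× on the recorded score. `true_beta` is therefore defined
  on the *observed* scale: the predictor contribution is centered and
  latent slopes are inflated by the reciprocal of the average
  derivative of clip(round(·)), estimated by a symmetric finite
  difference and solved by fixed point on the generated sample. OLS on
  large generated samples recovers planted effects within ~6%. The
  default planted truth is the six published predictors at their
  published per-subscale magnitudes (the printed positive sign on the
  partnership coefficient in the emotional model contradicts its
  negative CI and the abstract; the negative value is used).
- **Missingness.** Optional MCAR masking of predictor cells only
  (outcomes never masked by default); the source reports no
  missing-data mechanism, so nothing more structured is emulated.

The generator does **not** emulate: item-level responses for the
non-PCQ instruments (their scoring formulas are not public), realistic
block correlation among related predictors (e.g. comorbidity count vs
severity), missingness that depends on respondent characteristics, or
measurement error in the predictors. Consequently, passing tests show
that the *procedure* behaves correctly under the documented data
model — they do not certify its operating characteristics on the real
survey, whose dependence structure is richer.

## Problem sizes used in validation

Module tests run at n = 60–500 with reduced bootstrap counts; the
end-to-end checks use the study-scale conditions n = 487, B = 100,
k = 10, and moment-fidelity checks use n = 10,000. The acceptance
script runs the full four-outcome pipeline at n = 487 and the fidelity
block at n = 10,000; a complete run takes well under a minute on one
CPU thanks to the Gram-form compiled inner loop.

## Known limitations

- **Post-selection inference is naive by design.** The bootstrap CIs
  summarize the variability of the averaged penalized estimator; they
  are not selective-inference or debiased-LASSO intervals, and the
  package reproduces that convention rather than correcting it.
- **λ_min is liberal.** Cross-validated minimal penalties admit noise
  variables; within one survey of n = 487 a chance association persists
  across all bootstrap resamples of that survey, so single-dataset
  selection frequencies for null predictors can exceed 0.8. The 80%
  threshold controls resampling instability, not the chance of the
  original draw.
- **Weak effects straddle the threshold.** Planted effects whose
  observed-scale t-statistics are ≲2 at n = 487 (social support,
  health-literacy application, age on some scales, given the calibrated
  residual noise) reach the 80% line in some replicate surveys and fall
  short in others. Stable all-six selection of the published kind
  implies signal or predictor-dependence stronger than this generator's
  documented assumptions.
- **In-sample fit metrics.** RMSE/MAE are averaged in-sample values
  (matching the reporting convention reproduced here); out-of-bag
  metrics available via
  `refit_selected(..., metrics="oob")`, but are not the default report.
- The censoring-compensation fixed point is estimated per generated
  sample; at n = 487 its sampling noise adds a few percent of extra
  variability to realized effect sizes.
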