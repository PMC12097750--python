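# screenlasso

Bootstrap-stabilized LASSO selection of predictors of psychosocial
consequences of medical screening.

Screening asymptomatic adults (here: for early-stage liver cirrhosis and
fibrosis) can cause psychosocial harm — anxiety, social withdrawal,
physical complaints — measured by the Psychological Consequences of
Screening Questionnaire (PCQ: emotional 0–15, physical 0–12, social 0–9
subscales summing to a 0–36 total). These scores are floor-heavy,
right-skewed counts, and candidate predictors (comorbidity burden,
health literacy, social support, subjective social status,
sociodemographics — 24 in all) are modestly collinear. This package
implements, as a tested reusable pipeline, the bootstrap-stabilized
LASSO workflow used to identify reproducible predictors of such
outcomes, together with a calibrated synthetic survey generator so that
every stage can be exercised and validated at desk scale. It is aimed at
biostatisticians and health-services researchers who want the procedure
as an importable library rather than a one-off analysis script.

## Method

For each outcome *y* and standardized design *X* the core estimator is
the LASSO,

    min_β  (1/2n)·‖y − Xβ‖²₂ + λ·‖β‖₁ ,

solved by cyclic coordinate descent along a log-spaced path from
λ_max = max_j |x_jᵀy|/n, with λ chosen by 10-fold cross-validation
(λ_min, the grid value minimizing mean validation MSE). Selection is
stabilized by the bootstrap: B = 100 case resamples per outcome, a full
CV-LASSO on each, and a predictor is retained when its coefficient is
nonzero in at least 80% of the resamples. The retained set is refitted
with CV-LASSO on the same resamples; per-predictor coefficients are
averaged, their across-bootstrap standard deviation serves as the
standard error, and 95% confidence intervals are mean ± 1.96·SE. Model
fit is summarized by RMSE and MAE averaged over the bootstrap fitting
samples; a model is *well fitted on average* when RMSE < SD(y).
Group contrasts of the skewed outcome use the Mann–Whitney U test
(midranks, tie-corrected).

All coefficients are reported unstandardized (outcome points per
predictor unit); standardization is internal to the penalty and undone
before reporting.

## Worked example

`examples/05_final_models.py` runs the whole pipeline on one synthetic
survey (n = 487, the study's sample size, with the six published effect
magnitudes planted) for the emotional-dysfunction subscale:

```
     predictor  coefficient    se  ci_low  ci_high
 komo_severity         1.94 0.180    1.59     2.30
     macarthur        -0.38 0.100   -0.57    -0.18
           age        -0.05 0.014   -0.07    -0.02
   zap_quality        -0.71 0.238   -1.17    -0.24
       partner        -1.02 0.376   -1.75    -0.28
    komo_count        -0.21 0.085   -0.38    -0.04
          osss        -0.44 0.252   -0.93     0.06
household_size         0.33 0.166    0.00     0.65

RMSE 3.78 | outcome SD 4.59 | MAE 2.97 | well fitted: True
significant (CI excludes 0): ['komo_severity', 'macarthur', 'age',
 'zap_quality', 'partner', 'komo_count', 'household_size']
```

Each coefficient is an average over 100 bootstrap refits, in outcome
points per predictor unit: e.g. one point of comorbidity severity
raises expected emotional dysfunction by ≈1.9 points, while having a
steady partner lowers it by ≈1 point. The planted severity, social
status, age, partnership and support effects surface at the top;
`zap_quality`, `komo_count` and `household_size` illustrate that a
chance association within a single n = 487 draw can also pass the 80%
line. RMSE below the outcome SD marks the averaged model as informative.

The other examples cover simulation (`01`), PCQ scoring (`02`), a single
cross-validated fit (`03`), stability selection (`04`) and the
Mann–Whitney group comparison (`06`); each prints its results with a
short interpretation.

## Layout

- `src/screenlasso/schema.py` — variable schema (4 outcomes + 24 predictors), validation
- `src/screenlasso/scoring.py` — PCQ item scoring
- `src/screenlasso/simulate.py` — calibrated synthetic survey generator
- `src/screenlasso/lasso.py` — coordinate-descent LASSO, path, 10-fold CV
- `src/screenlasso/stability.py` — bootstrap selection frequencies, 80% threshold
- `src/screenlasso/inference.py` — final-model refits, bootstrap CIs, RMSE/MAE
- `src/screenlasso/groupstats.py` — descriptives, Mann–Whitney U
- `src/screenlasso/pipeline.py`, `cli.py` — orchestration, reports, thin CLI

See `docs/methods.md` for modeling assumptions, calibration details and
known limitations.
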