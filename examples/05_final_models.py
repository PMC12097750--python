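"""Full pipeline for one outcome: selection, refit, bootstrap inference.

After stability selection, the selected set is refitted with CV-LASSO on
the same 100 bootstrap resamples; coefficients are averaged, their
across-bootstrap SD serves as the standard error, and 95% CIs are
mean +/- 1.96*SE. A model counts as well fitted on average when its
averaged RMSE is below the outcome's standard deviation.
"""

from screenlasso import GeneratorConfig, run_pipeline
from screenlasso.pipeline import RunConfig

cfg = RunConfig(
    generator=GeneratorConfig(n=487, seed=11),
    outcomes=["pcq_emotional"],
    B=100, k=10, threshold=0.80, master_seed=1,
)
art = run_pipeline(cfg)
oa = art.outcomes["pcq_emotional"]

print(oa.final.to_frame().to_string(index=False))
print(f"\nRMSE {oa.final.rmse:.2f} | outcome SD {oa.final.outcome_sd:.2f} | "
      f"MAE {oa.final.mae:.2f} | well fitted: {oa.final.well_fitted}")
print(f"significant (CI excludes 0): {[n for n, s in oa.significant.items() if s]}")
print()
print("Each row is an averaged unstandardized coefficient: outcome points")
print("per predictor unit, with bootstrap SE and normal-approximation CI.")
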