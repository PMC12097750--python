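"""One cross-validated LASSO fit: penalty path, lambda_min, active set.

The LASSO solves min (1/(2n))||y - Xb||^2 + lambda*||b||_1 on
standardized predictors; 10-fold cross-validation picks the penalty
minimizing validation MSE, and coefficients are reported back in the
original measurement units.
"""

from screenlasso import GeneratorConfig, generate_dataset, cv_lasso, fit_lasso, standardize
from screenlasso.schema import default_schema, predictor_names

ds = generate_dataset(GeneratorConfig(n=487, seed=11))
preds = predictor_names(default_schema())

cv = cv_lasso(ds.frame, "pcq_emotional", preds, k=10, seed=1)
print(f"lambda grid: {cv.lambda_grid[0]:.3f} ... {cv.lambda_grid[-1]:.5f} "
      f"({len(cv.lambda_grid)} points)")
print(f"lambda_min = {cv.lambda_min:.4f}")

des = standardize(ds.frame[preds], ds.frame["pcq_emotional"])
fit = fit_lasso(des, cv.lambda_min)
active = {n: round(b, 3) for n, b in zip(fit.names, fit.beta_raw) if b != 0}
print(f"active set ({len(active)} of 24): {active}")
print()
print("Nonzero coefficients are in outcome points per predictor unit; the")
print("penalty has already shrunk the remaining candidates exactly to zero.")
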