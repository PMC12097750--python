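"""Final-model bootstrap inference after stability selection.

The selected predictors are refitted with CV-LASSO on the same B
bootstrap resamples (identical child-seed derivation, hence identical
resampled rows for a given master seed). Per-bootstrap raw coefficients
are averaged; their across-bootstrap standard deviation serves as the
standard error, and 95% confidence intervals are the normal-approximation
``mean +/- z * SE`` (z = 1.96 by default; percentile intervals are
available as an option). A predictor the penalty zeroes out within a
refit contributes that zero to the average — shrinkage is part of the
estimator being summarized.

Model fit is summarized by RMSE and MAE averaged over the bootstrap
fitting samples (in-sample, matching the averaged-performance
convention); a model counts as well fitted on average when the averaged
RMSE is below the outcome's standard deviation in the original
(non-resampled) analysis sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lasso import complete_cases, cv_lasso, fit_lasso, standardize
from .stability import SelectedSet, child_seed, _resample_indices

__all__ = [
    "CoefficientRecord",
    "FinalModel",
    "fit_metrics",
    "refit_selected",
    "summarize_final",
    "significance_flags",
    "ci_from_summary",
]

logger = logging.getLogger("screenlasso")


@dataclass
class CoefficientRecord:
    """Raw coefficients and in-sample fit errors for one bootstrap refit."""

    index: int
    coef: dict[str, float]
    intercept: float
    rmse: float
    mae: float


@dataclass
class FinalModel:
    """Bootstrap-averaged final model for one outcome."""

    outcome: str
    selected: SelectedSet
    coef_mean: dict[str, float]
    coef_se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    intercept_mean: float
    rmse: float
    mae: float
    outcome_sd: float
    z: float
    B: int

    @property
    def well_fitted(self) -> bool:
        return self.rmse < self.outcome_sd

    def to_frame(self, decimals: int = 2, se_decimals: int = 3) -> pd.DataFrame:
        """Report table: coefficient, SE, CI per selected predictor."""
        names = self.selected.names
        return pd.DataFrame(
            {
                "predictor": names,
                "coefficient": [round(self.coef_mean[n], decimals) for n in names],
                "se": [round(self.coef_se[n], se_decimals) for n in names],
                "ci_low": [round(self.ci_low[n], decimals) for n in names],
                "ci_high": [round(self.ci_high[n], decimals) for n in names],
            }
        )


def fit_metrics(y_obs: Sequence[float], y_pred: Sequence[float]) -> tuple[float, float]:
    """Root-mean-square error and mean absolute error of predictions."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size == 0 or y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must be equal-length, non-empty")
    err = y_obs - y_pred
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


def refit_selected(
    data: pd.DataFrame | "SurveyDataset",
    selected: SelectedSet,
    candidates: Optional[Sequence[str]] = None,
    B: int = 100,
    k: int = 10,
    master_seed: int = 0,
    n_lambda: int = 100,
    ratio: float = 1e-3,
    metrics: str = "insample",
) -> list[CoefficientRecord]:
    """CV-LASSO refits of the selected set on B bootstrap resamples.

    ``candidates`` (default: all schema predictors present) defines the
    complete-case analysis sample, so the refit uses exactly the rows
    the selection stage used. An empty selected set yields
    intercept-only records (a flagged degenerate model).

    ``metrics`` chooses where RMSE/MAE are evaluated: ``"insample"``
    (default, each bootstrap's own fitting sample — the averaged
    performance convention) or ``"oob"`` (the rows left out of the
    resample, a less optimistic estimate).
    """
    if metrics not in ("insample", "oob"):
        raise ValueError(f"unknown metrics mode {metrics!r}")
    frame = getattr(data, "frame", data)
    outcome = selected.outcome
    if candidates is None:
        from .schema import default_schema, predictor_names

        candidates = [c for c in predictor_names(default_schema()) if c in frame.columns]
        if not candidates:
            candidates = [c for c in frame.columns if c != outcome]
    sub = complete_cases(frame, [outcome, *candidates]).reset_index(drop=True)
    n = len(sub)
    names = selected.names
    if not names:
        logger.warning("refit_selected: empty selected set for %s; intercept-only", outcome)

    records: list[CoefficientRecord] = []
    for b in range(B):
        rng = np.random.default_rng(child_seed(master_seed, outcome, b, 0))
        idx = _resample_indices(rng, n)
        boot = sub.iloc[idx].reset_index(drop=True)
        if boot[outcome].nunique() == 1:
            idx = _resample_indices(rng, n)
            boot = sub.iloc[idx].reset_index(drop=True)
            if boot[outcome].nunique() == 1:
                logger.warning("refit bootstrap %d for %s: constant outcome; dropping", b, outcome)
                continue
        y = boot[outcome].to_numpy(dtype=float)
        oob = np.setdiff1d(np.arange(n), idx)
        if metrics == "oob" and oob.size == 0:  # pragma: no cover - astronomically rare
            logger.warning("refit bootstrap %d: no out-of-bag rows; using in-sample", b)
        eval_frame = sub.iloc[oob] if metrics == "oob" and oob.size else boot
        y_eval = eval_frame[outcome].to_numpy(dtype=float)
        if not names:
            rmse, mae = fit_metrics(y_eval, np.full(len(y_eval), y.mean()))
            records.append(CoefficientRecord(b, {}, float(y.mean()), rmse, mae))
            continue
        cv = cv_lasso(
            boot, outcome, names, k=k, n_lambda=n_lambda, ratio=ratio,
            seed=child_seed(master_seed, outcome, b, 1),
        )
        des = standardize(boot[names], y)
        fit = fit_lasso(des, cv.lambda_min)
        coef = dict.fromkeys(names, 0.0)
        coef.update(dict(zip(fit.names, fit.beta_raw)))
        rmse, mae = fit_metrics(y_eval, fit.predict(eval_frame[des.names]))
        records.append(CoefficientRecord(b, coef, fit.intercept_raw, rmse, mae))
    return records


def ci_from_summary(
    mean: float, se: float, z: float = 1.96, decimals: Optional[int] = None
) -> tuple[float, float]:
    """Normal-approximation confidence bounds ``mean +/- z*se``.

    With ``decimals`` set, bounds are rounded for reporting (the
    convention used in the printed result tables, 2 decimals).
    """
    lo, hi = mean - z * se, mean + z * se
    if decimals is not None:
        lo, hi = round(lo, decimals), round(hi, decimals)
    return lo, hi


def summarize_final(
    records: Sequence[CoefficientRecord],
    data: pd.DataFrame | "SurveyDataset",
    selected: SelectedSet,
    candidates: Optional[Sequence[str]] = None,
    z: float = 1.96,
    ci_method: str = "normal",
) -> FinalModel:
    """Average the bootstrap refits into a reportable final model.

    ``coef_se`` is the standard deviation of the per-bootstrap raw
    coefficients; the default CI is ``mean +/- z*SE``
    (``ci_method="percentile"`` uses the empirical 2.5/97.5 percent
    points instead). ``outcome_sd`` comes from the original analysis
    sample, not the resamples.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 bootstrap records to summarize")
    frame = getattr(data, "frame", data)
    outcome = selected.outcome
    if candidates is None:
        from .schema import default_schema, predictor_names

        candidates = [c for c in predictor_names(default_schema()) if c in frame.columns]
        if not candidates:
            candidates = [c for c in frame.columns if c != outcome]
    sub = complete_cases(frame, [outcome, *candidates])
    outcome_sd = float(sub[outcome].std(ddof=1))

    names = selected.names
    mat = np.array([[r.coef.get(nm, 0.0) for nm in names] for r in records])
    coef_mean = {nm: float(m) for nm, m in zip(names, mat.mean(axis=0))} if names else {}
    coef_se = {nm: float(s) for nm, s in zip(names, mat.std(axis=0, ddof=1))} if names else {}
    ci_low, ci_high = {}, {}
    for j, nm in enumerate(names):
        if ci_method == "normal":
            lo, hi = ci_from_summary(coef_mean[nm], coef_se[nm], z=z)
        elif ci_method == "percentile":
            lo, hi = np.percentile(mat[:, j], [2.5, 97.5])
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
        ci_low[nm], ci_high[nm] = float(lo), float(hi)

    return FinalModel(
        outcome=outcome,
        selected=selected,
        coef_mean=coef_mean,
        coef_se=coef_se,
        ci_low=ci_low,
        ci_high=ci_high,
        intercept_mean=float(np.mean([r.intercept for r in records])),
        rmse=float(np.mean([r.rmse for r in records])),
        mae=float(np.mean([r.mae for r in records])),
        outcome_sd=outcome_sd,
        z=z,
        B=len(records),
    )


def significance_flags(model: FinalModel) -> dict[str, bool]:
    """True where the CI excludes zero (inclusive endpoints cover 0)."""
    return {
        nm: not (model.ci_low[nm] <= 0.0 <= model.ci_high[nm])
        for nm in model.selected.names
    }
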