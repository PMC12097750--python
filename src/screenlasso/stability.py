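"""Bootstrap stability selection over cross-validated LASSO fits.

For each outcome, B case-resampled datasets (rows drawn with
replacement, resample size = n) are analyzed with CV-LASSO; a predictor
counts as relevant in a bootstrap when its coefficient at that
bootstrap's ``lambda_min`` is nonzero. Predictors whose selection
frequency reaches the threshold (default: at least 80% of bootstraps,
inclusive) form the selected set passed to the final-model refit.

Reproducibility: every random draw derives from a master seed through
``numpy.random.SeedSequence`` with entropy
``[master_seed, crc32(outcome), bootstrap_index, stream]``, so a run is
byte-identical under the same master seed and each outcome's bootstrap
stream is independent of the order outcomes are processed in.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lasso import complete_cases, cv_lasso, fit_lasso, standardize

__all__ = [
    "BootstrapRecord",
    "SelectionResult",
    "SelectedSet",
    "child_seed",
    "bootstrap_selection",
    "select_predictors",
    "frequency_ranking",
]

logger = logging.getLogger("screenlasso")


def child_seed(master_seed: int, outcome: str, b: int, stream: int) -> np.random.SeedSequence:
    """Deterministic per-(outcome, bootstrap, stream) seed derivation."""
    oc = zlib.crc32(outcome.encode()) & 0x7FFFFFFF
    return np.random.SeedSequence([master_seed & 0x7FFFFFFF, oc, b, stream])


@dataclass
class BootstrapRecord:
    """One bootstrap replicate: resample, chosen penalty, coefficients."""

    index: int
    row_indices: np.ndarray
    lambda_min: float
    coef: dict[str, float]  # raw (unstandardized) coefficients
    intercept: float


@dataclass
class SelectionResult:
    """Selection frequencies of every candidate over B bootstraps."""

    outcome: str
    B: int
    per_bootstrap: list[BootstrapRecord]
    frequency: dict[str, float]
    seed: int
    predictors: list[str]
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": list(self.frequency),
                "frequency": list(self.frequency.values()),
            }
        )


@dataclass
class SelectedSet:
    """Predictors meeting the frequency threshold, most stable first."""

    outcome: str
    threshold: float
    predictors: list[tuple[str, float]]  # (name, frequency), desc frequency

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.predictors]


def _resample_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, n, size=n)


def bootstrap_selection(
    data: pd.DataFrame | "SurveyDataset",
    outcome: str,
    predictors: Optional[Sequence[str]] = None,
    B: int = 100,
    k: int = 10,
    master_seed: int = 0,
    n_lambda: int = 100,
    ratio: float = 1e-3,
) -> SelectionResult:
    """Run CV-LASSO on B bootstrap resamples and tally selection.

    Complete cases on the outcome plus every candidate predictor are
    bootstrapped (case resampling with replacement, resample size n).
    A resample whose outcome is constant is redrawn once; if still
    degenerate the bootstrap is dropped and the frequency denominator
    reduced accordingly (with a logged warning).
    """
    frame = getattr(data, "frame", data)
    if predictors is None:
        from .schema import default_schema, predictor_names

        predictors = [c for c in predictor_names(default_schema()) if c in frame.columns]
        if not predictors:
            predictors = [c for c in frame.columns if c != outcome]
    predictors = list(predictors)
    sub = complete_cases(frame, [outcome, *predictors]).reset_index(drop=True)
    n = len(sub)
    if n < 10 * k:
        logger.warning(
            "bootstrap_selection: only %d complete cases for %s (>= %d recommended)",
            n, outcome, 10 * k,
        )

    records: list[BootstrapRecord] = []
    n_failed = 0
    for b in range(B):
        rng = np.random.default_rng(child_seed(master_seed, outcome, b, 0))
        idx = _resample_indices(rng, n)
        boot = sub.iloc[idx].reset_index(drop=True)
        if boot[outcome].nunique() == 1:
            idx = _resample_indices(rng, n)
            boot = sub.iloc[idx].reset_index(drop=True)
            if boot[outcome].nunique() == 1:
                logger.warning(
                    "bootstrap %d for %s: outcome constant after redraw; dropping", b, outcome
                )
                n_failed += 1
                continue
        cv = cv_lasso(
            boot, outcome, predictors, k=k, n_lambda=n_lambda, ratio=ratio,
            seed=child_seed(master_seed, outcome, b, 1),
        )
        des = standardize(boot[predictors], boot[outcome])
        fit = fit_lasso(des, cv.lambda_min)
        coef = dict.fromkeys(predictors, 0.0)
        coef.update(dict(zip(fit.names, fit.beta_raw)))
        logger.debug(
            "bootstrap %d outcome=%s lambda_min=%.5g active=%d",
            b, outcome, cv.lambda_min, sum(v != 0 for v in coef.values()),
        )
        records.append(
            BootstrapRecord(
                index=b, row_indices=idx, lambda_min=cv.lambda_min,
                coef=coef, intercept=fit.intercept_raw,
            )
        )
    denom = B - n_failed
    if denom == 0:
        raise ValueError(f"all {B} bootstraps failed for outcome {outcome!r}")
    frequency = {
        p: sum(r.coef[p] != 0.0 for r in records) / denom for p in predictors
    }
    return SelectionResult(
        outcome=outcome, B=B, per_bootstrap=records, frequency=frequency,
        seed=master_seed, predictors=predictors, n_failed=n_failed,
    )


def select_predictors(result: SelectionResult, threshold: float = 0.80) -> SelectedSet:
    """Keep predictors selected in at least ``threshold`` of bootstraps.

    The comparison is inclusive (frequency == threshold qualifies).
    Output is ordered by descending frequency; ties keep candidate
    (schema) order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    order = {p: i for i, p in enumerate(result.predictors)}
    chosen = [(p, f) for p, f in result.frequency.items() if f >= threshold]
    chosen.sort(key=lambda pf: (-pf[1], order[pf[0]]))
    return SelectedSet(outcome=result.outcome, threshold=threshold, predictors=chosen)


def frequency_ranking(
    results: Sequence[SelectionResult], threshold: float = 0.80
) -> pd.DataFrame:
    """Long table of per-outcome selection frequencies, ranked.

    One row per (outcome, predictor), sorted by descending frequency
    within outcome, with a boolean marking the threshold line.
    """
    if not results:
        raise ValueError("need at least one SelectionResult")
    rows = []
    for res in results:
        order = {p: i for i, p in enumerate(res.predictors)}
        ranked = sorted(res.frequency.items(), key=lambda pf: (-pf[1], order[pf[0]]))
        for rank, (p, f) in enumerate(ranked, start=1):
            rows.append(
                {
                    "outcome": res.outcome,
                    "rank": rank,
                    "predictor": p,
                    "frequency": f,
                    "selected": f >= threshold,
                }
            )
    return pd.DataFrame(rows)
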