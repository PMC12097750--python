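"""Descriptive statistics and the rank-based two-group comparison.

``describe`` reproduces the structure of a sample-characteristics
table: mean/SD for continuous variables, level percentages for binary
and few-level ordinal variables (mean/SD as well for ordinals, since
scales like subjective social status are conventionally summarized
both ways). ``mann_whitney_u`` compares an outcome between two groups
with the Mann-Whitney U test: midranks under ties, exact null
distribution on small tie-free samples, otherwise the tie-corrected
normal approximation with continuity correction (two-sided).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema import VariableSpec

__all__ = ["DescriptiveTable", "UTestResult", "describe", "mann_whitney_u", "compare_groups"]

# Table blocks for report layout (variables not listed fall in "other").
_BLOCKS = {
    "pcq_total": "outcomes", "pcq_emotional": "outcomes",
    "pcq_physical": "outcomes", "pcq_social": "outcomes",
    "koko_critical": "health", "koko_active": "health",
    "help_apply": "health", "help_interact": "health",
    "komo_count": "health", "komo_severity": "health",
    "screen_positive": "screening", "zap_trust": "screening",
    "zap_quality": "screening", "zap_satisfaction": "screening",
    "info_procedure": "screening", "info_risk": "screening",
    "good_hands": "screening", "received_result": "screening",
    "future_screening": "screening",
    "osss": "sociodemographics", "macarthur": "sociodemographics",
    "household_size": "sociodemographics", "partner": "sociodemographics",
    "school_degree": "sociodemographics", "prof_training": "sociodemographics",
    "employed": "sociodemographics", "sex": "sociodemographics",
    "age": "sociodemographics",
}

_MAX_PCT_LEVELS = 8  # level percentages only for scales at most this wide


@dataclass
class DescriptiveTable:
    """Sample descriptives: per-variable summary plus level percentages."""

    summary: pd.DataFrame  # variable, block, n, mean, sd
    levels: pd.DataFrame  # variable, level, percent (sums to 100 per variable)


def describe(data: pd.DataFrame | "SurveyDataset", schema: Iterable[VariableSpec]) -> DescriptiveTable:
    frame = getattr(data, "frame", data)
    srows, lrows = [], []
    for spec in schema:
        if spec.name not in frame.columns:
            continue
        col = pd.to_numeric(frame[spec.name], errors="coerce").dropna()
        block = _BLOCKS.get(spec.name, "other")
        srows.append(
            {
                "variable": spec.name,
                "block": block,
                "n": int(col.size),
                "mean": float(col.mean()) if col.size else np.nan,
                "sd": float(col.std(ddof=1)) if col.size > 1 else np.nan,
            }
        )
        n_levels = int(spec.hi - spec.lo) + 1
        if spec.vtype in ("binary", "ordinal") and n_levels <= _MAX_PCT_LEVELS and col.size:
            counts = col.value_counts()
            for level in range(int(spec.lo), int(spec.hi) + 1):
                lrows.append(
                    {
                        "variable": spec.name,
                        "level": level,
                        "percent": 100.0 * counts.get(level, 0) / col.size,
                    }
                )
    return DescriptiveTable(
        summary=pd.DataFrame(srows),
        levels=pd.DataFrame(lrows, columns=["variable", "level", "percent"]),
    )


@dataclass
class UTestResult:
    """Two-sample Mann-Whitney comparison with both U conventions."""

    u_statistic: float  # U for the first group (x)
    u_other: float  # U for the second group; u_statistic + u_other = n1*n2
    p_value: float
    group_means: tuple[float, float]
    group_ns: tuple[int, int]
    tie_corrected: bool
    method: str  # "exact" or "asymptotic"


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> UTestResult:
    """Two-sided Mann-Whitney U test of ``x`` versus ``y``.

    ``u_statistic`` is the number of (x, y) pairs won by ``x`` plus half
    the ties (midrank convention). The exact null distribution is used
    when ``n1*n2 <= 400`` and there are no ties across the pooled
    sample; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    return UTestResult(
        u_statistic=u_x,
        u_other=float(x.size * y.size) - u_x,
        p_value=float(res.pvalue),
        group_means=(float(x.mean()), float(y.mean())),
        group_ns=(int(x.size), int(y.size)),
        tie_corrected=has_ties and method == "asymptotic",
        method=method,
    )


def compare_groups(
    data: pd.DataFrame | "SurveyDataset", outcome: str, group: str
) -> UTestResult:
    """Mann-Whitney comparison of ``outcome`` across a binary ``group``.

    The group coded 1 (e.g. positively screened) is the first sample, so
    ``u_statistic`` refers to it.
    """
    frame = getattr(data, "frame", data)
    sub = frame[[outcome, group]].dropna()
    x = sub.loc[sub[group] == 1, outcome]
    y = sub.loc[sub[group] != 1, outcome]
    return mann_whitney_u(x, y)
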