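"""End-to-end orchestration: data -> validation -> selection -> final models.

A :class:`RunConfig` names either an input CSV or a generator
configuration, the outcomes to model, and the procedure constants
(B bootstraps, k CV folds, selection threshold, CI z). ``run_pipeline``
executes, per outcome: validation report, bootstrap stability
selection, thresholding, final-model refit and summary. All randomness
derives from one master seed (see stability.child_seed), so identical
config + seed reproduces identical artifacts. ``render_reports`` writes
the descriptives table, the per-outcome frequency ranking, a
final-model table (CSV and aligned text) and a JSON manifest from which
the run can be reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from importlib.metadata import version as _dist_version

from .groupstats import DescriptiveTable, describe
from .inference import FinalModel, refit_selected, significance_flags, summarize_final
from .schema import ValidationReport, default_schema, predictor_names, validate_dataset
from .simulate import GeneratorConfig, SurveyDataset, generate_dataset
from .stability import (
    SelectedSet,
    SelectionResult,
    bootstrap_selection,
    frequency_ranking,
    select_predictors,
)

__all__ = ["RunConfig", "RunArtifacts", "run_pipeline", "render_reports"]

logger = logging.getLogger("screenlasso")

_PCQ_OUTCOMES = ["pcq_total", "pcq_emotional", "pcq_social", "pcq_physical"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_csv: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    outcomes: list[str] = field(default_factory=lambda: list(_PCQ_OUTCOMES))
    B: int = 100
    k: int = 10
    threshold: float = 0.80
    z: float = 1.96
    master_seed: int = 0
    n_lambda: int = 100
    lambda_ratio: float = 1e-3
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be at least 2")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        if self.input_csv is None and self.generator is None:
            self.generator = GeneratorConfig(seed=self.master_seed)


@dataclass
class OutcomeArtifacts:
    outcome: str
    selection: SelectionResult
    selected: SelectedSet
    final: FinalModel
    significant: dict[str, bool]


@dataclass
class RunArtifacts:
    config: RunConfig
    data: SurveyDataset
    validation: ValidationReport
    descriptives: DescriptiveTable
    outcomes: dict[str, OutcomeArtifacts]
    manifest: dict


def _load_input(cfg: RunConfig) -> SurveyDataset:
    if cfg.input_csv is not None:
        frame = pd.read_csv(cfg.input_csv)
        digest = hashlib.sha256(Path(cfg.input_csv).read_bytes()).hexdigest()[:16]
        return SurveyDataset(
            frame=frame, schema=default_schema(),
            provenance={"input_csv": str(cfg.input_csv), "sha256": digest},
        )
    return generate_dataset(cfg.generator)


def run_pipeline(cfg: RunConfig) -> RunArtifacts:
    """Execute the full bootstrap-stabilized LASSO analysis."""
    data = _load_input(cfg)
    schema = data.schema
    candidates = [c for c in predictor_names(schema) if c in data.frame.columns]
    validation = validate_dataset(data.frame, schema)
    if validation.n_violations:
        logger.warning("validation: %d range/type violations", validation.n_violations)
    descriptives = describe(data, schema)

    results: dict[str, OutcomeArtifacts] = {}
    for outcome in cfg.outcomes:
        logger.info("outcome %s: stability selection (B=%d, k=%d)", outcome, cfg.B, cfg.k)
        selection = bootstrap_selection(
            data.frame, outcome, candidates, B=cfg.B, k=cfg.k,
            master_seed=cfg.master_seed, n_lambda=cfg.n_lambda, ratio=cfg.lambda_ratio,
        )
        selected = select_predictors(selection, threshold=cfg.threshold)
        records = refit_selected(
            data.frame, selected, candidates, B=cfg.B, k=cfg.k,
            master_seed=cfg.master_seed, n_lambda=cfg.n_lambda, ratio=cfg.lambda_ratio,
        )
        final = summarize_final(records, data.frame, selected, candidates, z=cfg.z)
        results[outcome] = OutcomeArtifacts(
            outcome=outcome, selection=selection, selected=selected,
            final=final, significant=significance_flags(final),
        )

    manifest = {
        "package": "screenlasso",
        "version": _dist_version("screenlasso"),
        "master_seed": cfg.master_seed,
        "config": _config_dict(cfg),
        "input": data.provenance,
        "n_rows": data.n,
    }
    return RunArtifacts(
        config=cfg, data=data, validation=validation,
        descriptives=descriptives, outcomes=results, manifest=manifest,
    )


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    if cfg.generator is not None:
        g = dataclasses.asdict(cfg.generator)
        g["schema"] = [dataclasses.asdict(s) for s in cfg.generator.schema]
        d["generator"] = g
    return d


def _final_table_text(models: dict[str, FinalModel]) -> str:
    """Aligned plain-text final-model table with RMSE/SD/MAE footer."""
    lines = []
    for outcome, m in models.items():
        lines.append(f"== {outcome} ==")
        if not m.selected.names:
            lines.append("  (no predictors selected; intercept-only model)")
        else:
            lines.append(f"  {'predictor':<18}{'coef':>8}{'se':>8}  95% CI")
            for nm in m.selected.names:
                lines.append(
                    f"  {nm:<18}{m.coef_mean[nm]:>8.2f}{m.coef_se[nm]:>8.3f}"
                    f"  [{m.ci_low[nm]:.2f}; {m.ci_high[nm]:.2f}]"
                )
        lines.append(f"  {'RMSE':<18}{m.rmse:>8.2f}")
        lines.append(f"  {'outcome SD':<18}{m.outcome_sd:>8.2f}")
        lines.append(f"  {'MAE':<18}{m.mae:>8.2f}")
        lines.append(f"  well fitted on average: {'yes' if m.well_fitted else 'no'}")
        lines.append("")
    return "\n".join(lines)


def render_reports(artifacts: RunArtifacts, outdir: str | Path, plot: bool = False) -> dict[str, Path]:
    """Write descriptives, frequency ranking, final models and manifest.

    Returns a name -> path map of everything written. With
    ``plot=True`` (requires matplotlib) a frequency-ranking figure is
    saved as well.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["descriptives"] = outdir / "descriptives.csv"
    artifacts.descriptives.summary.to_csv(files["descriptives"], index=False)
    files["level_percentages"] = outdir / "level_percentages.csv"
    artifacts.descriptives.levels.to_csv(files["level_percentages"], index=False)

    ranking = frequency_ranking(
        [oa.selection for oa in artifacts.outcomes.values()],
        threshold=artifacts.config.threshold,
    )
    files["frequency_ranking"] = outdir / "frequency_ranking.csv"
    ranking.to_csv(files["frequency_ranking"], index=False)

    rows = []
    for outcome, oa in artifacts.outcomes.items():
        m = oa.final
        for nm in m.selected.names:
            rows.append(
                {
                    "outcome": outcome, "predictor": nm,
                    "coefficient": round(m.coef_mean[nm], 2),
                    "se": round(m.coef_se[nm], 3),
                    "ci_low": round(m.ci_low[nm], 2),
                    "ci_high": round(m.ci_high[nm], 2),
                    "significant": oa.significant[nm],
                    "frequency": dict(oa.selected.predictors)[nm],
                }
            )
        rows.append({"outcome": outcome, "predictor": "_RMSE", "coefficient": round(m.rmse, 2)})
        rows.append({"outcome": outcome, "predictor": "_outcome_SD", "coefficient": round(m.outcome_sd, 2)})
        rows.append({"outcome": outcome, "predictor": "_MAE", "coefficient": round(m.mae, 2)})
    files["final_models"] = outdir / "final_models.csv"
    pd.DataFrame(rows).to_csv(files["final_models"], index=False)

    files["final_models_txt"] = outdir / "final_models.txt"
    files["final_models_txt"].write_text(
        _final_table_text({o: oa.final for o, oa in artifacts.outcomes.items()}),
        encoding="utf-8",
    )

    files["manifest"] = outdir / "manifest.json"
    files["manifest"].write_text(
        json.dumps(artifacts.manifest, indent=2, sort_keys=True, default=str),
        encoding="utf-8",
    )

    if plot:
        files["frequency_plot"] = _plot_ranking(ranking, artifacts.config.threshold, outdir)
    return files


def _plot_ranking(ranking: pd.DataFrame, threshold: float, outdir: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outcomes = ranking["outcome"].unique()
    fig, axes = plt.subplots(1, len(outcomes), figsize=(4 * len(outcomes), 6), sharex=True)
    if len(outcomes) == 1:
        axes = [axes]
    for ax, outcome in zip(axes, outcomes):
        sub = ranking[ranking["outcome"] == outcome].sort_values("frequency")
        ax.barh(sub["predictor"], sub["frequency"])
        ax.axvline(threshold, color="red", linestyle="--", linewidth=1)
        ax.set_title(outcome)
        ax.set_xlabel("selection frequency")
    fig.tight_layout()
    path = outdir / "frequency_ranking.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
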