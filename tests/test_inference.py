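import numpy as np
import pandas as pd
import pytest

from screenlasso.inference import (
    ci_from_summary,
    fit_metrics,
    refit_selected,
    significance_flags,
    summarize_final,
)
from screenlasso.simulate import GeneratorConfig, generate_dataset
from screenlasso.stability import SelectedSet


class TestFitMetrics:
    def test_perfect_prediction_is_zero_error(self):
        assert fit_metrics([1, 2, 3], [1, 2, 3]) == (0.0, 0.0)

    def test_constant_offset_gives_equal_rmse_and_mae(self):
        rmse, mae = fit_metrics([0, 1, 2], [1.5, 2.5, 3.5])
        assert rmse == pytest.approx(1.5)
        assert mae == pytest.approx(1.5)

    def test_hand_computed_example(self):
        rmse, mae = fit_metrics([0, 0, 3], [1, 0, 1])
        assert rmse == pytest.approx(np.sqrt(5 / 3))
        assert mae == pytest.approx(1.0)

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            fit_metrics([], [])

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            y = rng.standard_normal(30)
            pred = y + rng.standard_normal(30)
            rmse, mae = fit_metrics(y, pred)
            assert rmse >= mae >= 0


class TestCiArithmetic:
    @pytest.mark.parametrize(
        "mean, se, expected",
        [
            (2.72, 0.066, (2.59, 2.85)),  # severity, total-score model
            (1.47, 0.032, (1.41, 1.53)),  # severity, emotional model
            (0.94, 0.022, (0.90, 0.98)),  # severity, physical model
        ],
    )
    def test_reproduces_published_bounds_at_two_decimals(self, mean, se, expected):
        assert ci_from_summary(mean, se, z=1.96, decimals=2) == expected

    def test_zero_se_collapses_interval(self):
        assert ci_from_summary(1.5, 0.0) == (1.5, 1.5)


class TestSignificanceFlags:
    def _model(self, lo, hi):
        sel = SelectedSet(outcome="y", threshold=0.8, predictors=[("a", 0.9)])
        from screenlasso.inference import FinalModel

        return FinalModel(
            outcome="y", selected=sel, coef_mean={"a": (lo + hi) / 2},
            coef_se={"a": 0.1}, ci_low={"a": lo}, ci_high={"a": hi},
            intercept_mean=0.0, rmse=1.0, mae=0.8, outcome_sd=2.0, z=1.96, B=100,
        )

    def test_interval_excluding_zero_is_significant(self):
        assert significance_flags(self._model(2.59, 2.85)) == {"a": True}

    def test_interval_covering_zero_is_not(self):
        assert significance_flags(self._model(-0.1, 0.1)) == {"a": False}

    def test_boundary_zero_counts_as_covered(self):
        assert significance_flags(self._model(0.0, 0.2)) == {"a": False}


@pytest.fixture(scope="module")
def severity_only_dataset():
    """Planted comorbidity-severity effect of 2.7 on the total score."""
    share = 2.7 / 2.85
    cfg = GeneratorConfig(
        n=487, seed=31,
        true_beta={
            "pcq_emotional": {"komo_severity": 1.47 * share},
            "pcq_social": {"komo_severity": 0.44 * share},
            "pcq_physical": {"komo_severity": 0.94 * share},
        },
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="module")
def severity_records(severity_only_dataset):
    sel = SelectedSet(outcome="pcq_total", threshold=0.8, predictors=[("komo_severity", 1.0)])
    return sel, refit_selected(severity_only_dataset.frame, sel, B=100, k=10, master_seed=12)


class TestRefitSelected:
    def test_one_record_per_bootstrap(self, severity_records):
        _, records = severity_records
        assert len(records) == 100
        for rec in records[:5]:
            assert set(rec.coef) == {"komo_severity"}
            assert rec.rmse >= rec.mae >= 0

    def test_planted_effect_recovered_within_three_se(self, severity_records, severity_only_dataset):
        sel, records = severity_records
        model = summarize_final(records, severity_only_dataset.frame, sel)
        err = abs(model.coef_mean["komo_severity"] - 2.7)
        assert err < 3 * model.coef_se["komo_severity"]

    def test_noise_free_signal_fits_to_rounding_error(self):
        # zero residual noise and an interior intercept: the only error
        # left is integer rounding of the latent scale.
        zero = {k: 0.0 for k in ("pcq_emotional", "pcq_physical", "pcq_social")}
        cfg = GeneratorConfig(
            n=300, seed=5,
            true_beta={"pcq_emotional": {"komo_severity": 0.8}},
            intercepts={"pcq_emotional": 7.0, "pcq_physical": 6.0, "pcq_social": 4.0},
            noise_sd=zero,
        )
        ds = generate_dataset(cfg)
        sel = SelectedSet(outcome="pcq_emotional", threshold=0.8, predictors=[("komo_severity", 1.0)])
        records = refit_selected(ds.frame, sel, B=10, k=10, master_seed=2)
        assert all(rec.rmse < 0.5 for rec in records)

    def test_out_of_bag_metrics_use_same_fits_on_heldout_rows(self, severity_only_dataset):
        sel = SelectedSet(outcome="pcq_total", threshold=0.8, predictors=[("komo_severity", 1.0)])
        ins = refit_selected(severity_only_dataset.frame, sel, B=20, k=10, master_seed=12)
        oob = refit_selected(
            severity_only_dataset.frame, sel, B=20, k=10, master_seed=12, metrics="oob"
        )
        # identical resamples and fits, different evaluation rows
        assert all(a.coef == b.coef for a, b in zip(ins, oob))
        assert any(a.rmse != b.rmse for a, b in zip(ins, oob))
        assert all(r.rmse >= r.mae >= 0 for r in oob)

    def test_empty_selection_yields_intercept_only_records(self, survey487):
        sel = SelectedSet(outcome="pcq_total", threshold=0.8, predictors=[])
        records = refit_selected(survey487.frame, sel, B=5, k=5, master_seed=1)
        assert len(records) == 5
        assert all(rec.coef == {} for rec in records)


class TestSummarizeFinal:
    def test_summary_structure_and_well_fitted_flag(self, severity_records, severity_only_dataset):
        sel, records = severity_records
        model = summarize_final(records, severity_only_dataset.frame, sel)
        nm = "komo_severity"
        assert model.ci_low[nm] <= model.coef_mean[nm] <= model.ci_high[nm]
        assert model.rmse >= model.mae >= 0
        assert model.well_fitted == (model.rmse < model.outcome_sd)
        assert model.B == 100

    def test_percentile_interval_option(self, severity_records, severity_only_dataset):
        sel, records = severity_records
        model = summarize_final(
            records, severity_only_dataset.frame, sel, ci_method="percentile"
        )
        nm = "komo_severity"
        assert model.ci_low[nm] < model.coef_mean[nm] < model.ci_high[nm]

    def test_needs_at_least_two_records(self, severity_records, severity_only_dataset):
        sel, records = severity_records
        with pytest.raises(ValueError):
            summarize_final(records[:1], severity_only_dataset.frame, sel)
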