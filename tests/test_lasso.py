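import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Lasso

from screenlasso.lasso import (
    CvResult,
    PathError,
    StandardizedDesign,
    complete_cases,
    cv_lasso,
    fit_lasso,
    fit_path,
    lambda_max,
    lambda_path,
    soft_threshold,
    standardize,
)


def _objective(design, beta, lam):
    r = design.y_centered - design.X_std @ beta
    return r @ r / (2 * design.n) + lam * np.abs(beta).sum()


def _random_design(rng, n, p, snr=1.0):
    X = rng.standard_normal((n, p)) @ (np.eye(p) + 0.3 * rng.standard_normal((p, p)))
    beta = rng.standard_normal(p) * (rng.random(p) < 0.6)
    y = X @ beta * snr + rng.standard_normal(n)
    return standardize(X, y)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "z, gamma, expected", [(3, 1, 2), (-0.5, 1, 0), (-3, 1, -2), (0, 0, 0), (2.5, 0, 2.5)]
    )
    def test_closed_form(self, z, gamma, expected):
        assert soft_threshold(z, gamma) == pytest.approx(expected)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestStandardize:
    def test_columns_mean_zero_unit_sd(self, rng):
        des = _random_design(rng, 60, 5)
        assert np.abs(des.X_std.mean(axis=0)).max() < 1e-10
        assert np.abs(des.X_std.std(axis=0) - 1).max() < 1e-10

    def test_zero_variance_column_dropped_and_recorded(self, rng):
        X = rng.standard_normal((30, 3))
        X[:, 1] = 7.0
        des = standardize(X, rng.standard_normal(30), names=["a", "b", "c"])
        assert des.dropped == ["b"]
        assert des.names == ["a", "c"]


class TestFitLasso:
    def test_penalty_at_lambda_max_zeroes_everything(self, rng):
        des = _random_design(rng, 50, 4)
        fit = fit_lasso(des, lambda_max(des))
        assert np.all(fit.beta_std == 0.0)
        assert fit.intercept_raw == pytest.approx(des.y_mean)

    def test_orthogonal_design_matches_soft_threshold_closed_form(self, rng):
        n, p = 64, 4
        raw = rng.standard_normal((n, p))
        raw -= raw.mean(axis=0)
        Q, _ = np.linalg.qr(raw)
        X = Q * np.sqrt(n)  # columns: mean ~0, SD 1, mutually orthogonal
        y = rng.standard_normal(n) + X @ np.array([1.0, -0.5, 0.0, 0.2])
        des = standardize(X, y)
        lam = 0.3
        fit = fit_lasso(des, lam, tol=1e-12)
        closed = np.array(
            [soft_threshold(des.X_std[:, j] @ des.y_centered / n, lam) for j in range(p)]
        )
        assert np.abs(fit.beta_std - closed).max() < 1e-8

    def test_objective_matches_sklearn_oracle(self, rng):
        for _ in range(5):
            des = _random_design(rng, 25, 4)
            lam = float(rng.uniform(0.01, 0.5))
            mine = fit_lasso(des, lam, tol=1e-10)
            oracle = Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=500_000)
            oracle.fit(des.X_std, des.y_centered)
            assert _objective(des, mine.beta_std, lam) <= _objective(des, oracle.coef_, lam) + 1e-6

    def test_back_transformed_predictions_match_standardized(self, rng):
        X = rng.standard_normal((40, 3)) * np.array([10.0, 0.1, 1.0]) + np.array([5.0, -2.0, 0.0])
        y = X @ np.array([0.5, -3.0, 1.0]) + rng.standard_normal(40)
        des = standardize(X, y)
        fit = fit_lasso(des, 0.05, tol=1e-12)
        pred_std = des.y_mean + des.X_std @ fit.beta_std
        pred_raw = fit.predict(X)
        assert np.abs(pred_raw - pred_std).max() < 1e-8

    def test_debug_reference_agrees_with_jitted_kernel(self, rng):
        des = _random_design(rng, 30, 5)
        fit_fast = fit_lasso(des, 0.1, tol=1e-10)
        fit_ref = fit_lasso(des, 0.1, tol=1e-10, debug=True)  # asserts monotone objective
        assert np.abs(fit_fast.beta_std - fit_ref.beta_std).max() < 1e-7


class TestLambdaPath:
    def test_single_predictor_formula(self):
        # x'y/n = 0.8 by construction
        n = 10
        x = np.ones(n)
        x[: n // 2] = -1.0
        y = 0.8 * x
        des = StandardizedDesign(
            X_std=x[:, None], y_centered=y, col_means=np.zeros(1),
            col_sds=np.ones(1), y_mean=0.0, names=["x"],
        )
        assert lambda_max(des) == pytest.approx(0.8)

    def test_grid_is_strictly_decreasing_with_requested_length(self, rng):
        des = _random_design(rng, 40, 3)
        grid = lambda_path(des, n_lambda=100, ratio=0.001)
        assert len(grid) == 100
        assert np.all(np.diff(grid) < 0)
        assert grid[0] == pytest.approx(lambda_max(des))
        assert grid[-1] == pytest.approx(0.001 * grid[0])

    def test_constant_response_raises_path_error(self, rng):
        X = rng.standard_normal((20, 3))
        with pytest.raises(PathError, match="degenerate"):
            lambda_path(standardize(X, np.full(20, 3.0)))

    def test_active_set_grows_from_empty_along_path(self, rng):
        des = _random_design(rng, 50, 5)
        grid = lambda_path(des, n_lambda=30)
        coefs = fit_path(des, grid)
        assert np.all(coefs[0] == 0.0)
        first = set(np.flatnonzero(coefs[0]))
        last = set(np.flatnonzero(coefs[-1]))
        assert first <= last

    def test_active_set_size_weakly_monotone_along_path(self, rng):
        agree = total = 0
        for _ in range(10):
            des = _random_design(rng, 60, 5)
            sizes = (fit_path(des, lambda_path(des, n_lambda=50)) != 0).sum(axis=1)
            agree += int((np.diff(sizes) >= 0).sum())
            total += len(sizes) - 1
        assert agree / total >= 0.95


class TestCvLasso:
    def test_same_seed_gives_identical_result(self, survey487, predictors):
        a = cv_lasso(survey487.frame, "pcq_total", predictors, seed=3)
        b = cv_lasso(survey487.frame, "pcq_total", predictors, seed=3)
        assert a.lambda_min == b.lambda_min
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_array_equal(a.cv_mean, b.cv_mean)

    def test_fold_sizes_balanced(self, rng):
        X = rng.standard_normal((100, 3))
        y = X[:, 0] + rng.standard_normal(100)
        frame = pd.DataFrame(np.column_stack([y, X]), columns=["y", "a", "b", "c"])
        cv = cv_lasso(frame, "y", ["a", "b", "c"], k=10, seed=1)
        sizes = np.bincount(cv.fold_assignment)
        assert (sizes == 10).all()

    def test_lambda_min_lies_on_grid(self, survey487, predictors):
        cv = cv_lasso(survey487.frame, "pcq_emotional", predictors, seed=2)
        assert cv.lambda_min in cv.lambda_grid
        assert np.isfinite(cv.cv_mean).all()

    def test_too_few_rows_rejected(self, rng):
        frame = pd.DataFrame({"y": rng.standard_normal(5), "x": rng.standard_normal(5)})
        with pytest.raises(ValueError, match="complete cases"):
            cv_lasso(frame, "y", ["x"], k=10)

    def test_strong_signal_recovered_at_lambda_min(self, rng):
        # 3 true predictors at 5x the noise SD: the active set at the
        # CV-selected penalty must contain all three nearly always.
        hits = 0
        runs = 40
        for i in range(runs):
            X = rng.standard_normal((300, 10))
            y = 5.0 * (X[:, 0] + X[:, 1] + X[:, 2]) + rng.standard_normal(300)
            cols = [f"x{j}" for j in range(10)]
            frame = pd.DataFrame(X, columns=cols)
            frame["y"] = y
            cv = cv_lasso(frame, "y", cols, k=10, seed=i)
            fit = fit_lasso(standardize(X, y, names=cols), cv.lambda_min)
            if {"x0", "x1", "x2"} <= set(fit.active_set()):
                hits += 1
        assert hits / runs >= 0.95


def test_complete_cases_filters_rows_with_any_missing():
    frame = pd.DataFrame({"y": [1.0, 2.0, np.nan], "x": [1.0, np.nan, 3.0]})
    sub = complete_cases(frame, ["y", "x"])
    assert len(sub) == 1
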