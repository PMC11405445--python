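"""Median-regression solver: exactness, invariances, bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hoicost import bootstrap_se, fit_median_regression
from hoicost.stage1 import l1_objective


def brute_force_l1_minimum(X: np.ndarray, y: np.ndarray) -> float:
    """Independent oracle: an L1-optimal fit passes through p+1 points, so
    enumerate every exact-fit hyperplane through p+1 points and take the
    smallest objective."""
    n, p = X.shape
    best = np.inf
    for idx in itertools.combinations(range(n), p):
        A = X[list(idx)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        beta = np.linalg.solve(A, y[list(idx)])
        best = min(best, float(np.abs(y - X @ beta).sum()))
    return best


def _frame(x_cols: dict, y: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame(x_cols)
    df["cost"] = y
    return df


def test_intercept_only_fit_is_the_sample_median():
    df = _frame({}, np.array([1.0, 2.0, 100.0]))
    fit = fit_median_regression(df, covariates=[])
    assert fit.estimates["intercept"] == pytest.approx(2.0)


@pytest.mark.parametrize("p", [1, 2])
def test_lp_objective_matches_brute_force_enumeration(p):
    """On every small instance the LP attains the enumeration minimum."""
    rng = np.random.default_rng(2024)
    for trial in range(25):
        n = int(rng.integers(p + 2, 11))
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        beta = rng.normal(size=p + 1) * 3
        y = X @ beta + rng.standard_t(3, size=n)
        cols = {f"x{j}": X[:, j + 1] for j in range(p)}
        fit = fit_median_regression(_frame(cols, y), covariates=list(cols))
        oracle = brute_force_l1_minimum(X, y)
        assert fit.objective == pytest.approx(oracle, rel=1e-8, abs=1e-10)


def test_solution_survives_coordinate_perturbation():
    """No single-coefficient nudge of +-eps lowers the L1 objective."""
    rng = np.random.default_rng(5)
    n = 200
    df = _frame(
        {"x1": rng.normal(size=n), "x2": rng.exponential(size=n)},
        rng.normal(size=n) * 10 + 3,
    )
    fit = fit_median_regression(df, covariates=["x1", "x2"])
    base = l1_objective(df, fit.estimates, covariates=["x1", "x2"])
    for term in fit.estimates:
        scale = max(abs(fit.estimates[term]), 1.0)
        for sign in (+1, -1):
            bumped = dict(fit.estimates)
            bumped[term] += sign * 1e-4 * scale
            assert l1_objective(df, bumped, covariates=["x1", "x2"]) >= base - 1e-9 * base


def test_scale_and_shift_equivariance():
    rng = np.random.default_rng(11)
    n = 120
    df = _frame({"x1": rng.normal(size=n)}, rng.lognormal(size=n) * 50)
    fit = fit_median_regression(df, covariates=["x1"])
    lam, delta = 3.5, 250.0
    scaled = df.assign(cost=df["cost"] * lam)
    shifted = df.assign(cost=df["cost"] + delta)
    fit_scaled = fit_median_regression(scaled, covariates=["x1"])
    fit_shifted = fit_median_regression(shifted, covariates=["x1"])
    for term in fit.estimates:
        assert fit_scaled.estimates[term] == pytest.approx(
            lam * fit.estimates[term], rel=1e-6, abs=1e-8
        )
    assert fit_shifted.estimates["intercept"] == pytest.approx(
        fit.estimates["intercept"] + delta, rel=1e-6
    )
    assert fit_shifted.estimates["x1"] == pytest.approx(
        fit.estimates["x1"], rel=1e-6, abs=1e-8
    )


def test_agrees_with_independent_quantile_regression():
    """statsmodels QuantReg(q=0.5) as an independent route to the same
    objective (coefficients may differ at ties; objectives must not)."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(17)
    n = 400
    X = rng.normal(size=(n, 3))
    y = 5 + X @ np.array([2.0, -1.0, 0.5]) + rng.lognormal(sigma=0.8, size=n)
    df = _frame({f"x{j}": X[:, j] for j in range(3)}, y)
    fit = fit_median_regression(df, covariates=["x0", "x1", "x2"])
    qr = sm.QuantReg(y, sm.add_constant(X)).fit(q=0.5)
    qr_obj = float(np.abs(y - sm.add_constant(X) @ qr.params).sum())
    assert fit.objective <= qr_obj * (1 + 1e-9)
    assert fit.objective == pytest.approx(qr_obj, rel=1e-4)


def test_collinear_design_is_rejected_by_name():
    rng = np.random.default_rng(3)
    x = rng.normal(size=30)
    df = _frame({"x1": x, "x2": 2 * x}, rng.normal(size=30))
    with pytest.raises(ValueError, match="x2"):
        fit_median_regression(df, covariates=["x1", "x2"])


def test_underdetermined_fit_is_rejected():
    df = _frame({"x1": np.array([1.0, 2.0])}, np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        fit_median_regression(df, covariates=["x1"])


def test_empty_cohort_is_rejected():
    with pytest.raises(ValueError):
        fit_median_regression(_frame({}, np.array([])), covariates=[])


def test_reference_dummy_rows_are_structural_zeros():
    rng = np.random.default_rng(9)
    n = 60
    df = _frame(
        {
            "urban_teaching": rng.integers(0, 2, n).astype(float),
            "small_bedsize": rng.integers(0, 2, n).astype(float),
        },
        rng.normal(size=n) * 100,
    )
    fit = fit_median_regression(df, covariates=["urban_teaching", "small_bedsize"])
    table = fit.to_frame(reference_rows=True)
    zeros = table.loc[table["term"].str.endswith("_ref")]
    assert len(zeros) == 2 and (zeros["estimate"] == 0).all()


class TestBootstrap:
    def test_same_seed_reproduces_intervals(self):
        rng = np.random.default_rng(21)
        df = _frame({"x1": rng.normal(size=80)}, rng.normal(size=80) * 5)
        a = bootstrap_se(df, covariates=["x1"], B=50, seed=4)
        b = bootstrap_se(df, covariates=["x1"], B=50, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_costs_give_zero_se_and_point_interval(self):
        df = _frame({}, np.full(20, 7.0))
        out = bootstrap_se(df, covariates=[], B=30, seed=0)
        assert out.loc["intercept", "se"] == 0.0
        assert out.loc["intercept", "ci_low"] == 7.0
        assert out.loc["intercept", "ci_high"] == 7.0

    def test_too_few_replicates_rejected(self):
        df = _frame({}, np.arange(10.0))
        with pytest.raises(ValueError):
            bootstrap_se(df, covariates=[], B=1)

    def test_interval_covers_generating_slope(self):
        """Percentile CIs cover the true slope in >= 90% of replicates."""
        rng = np.random.default_rng(31)
        hits = 0
        reps = 30
        for _ in range(reps):
            x = rng.normal(size=150)
            y = 2.0 + 3.0 * x + rng.standard_t(4, size=150)
            df = _frame({"x1": x}, y)
            out = bootstrap_se(
                df, covariates=["x1"], B=120, seed=int(rng.integers(2**31))
            )
            if out.loc["x1", "ci_low"] <= 3.0 <= out.loc["x1", "ci_high"]:
                hits += 1
        assert hits >= 0.9 * reps
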