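"""Ridge initialization, smooth-thresholding fits, lambda path, EBIC."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import episis.stlogit as stl
from episis.stlogit import (
    ConvergenceError,
    EbicConfig,
    RidgeInit,
    adaptive_ridge_init,
    ebic,
    fit_path,
    lambda_path,
    ridge_logistic,
    select_from_path,
    select_model,
    st_fit,
    st_weights,
)


def _logit_data(seed, n=60, d=4, beta=None, intercept=-0.2):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, d)).astype(float)
    if beta is None:
        beta = np.zeros(d)
    eta = intercept + X @ beta
    y = (rng.random(n) < expit(eta)).astype(float)
    if y.sum() in (0, n):
        y[0], y[-1] = 1.0, 0.0
    return X, y


def _negll(X, y, b):
    eta = b[0] + X @ b[1:]
    return float(np.sum(np.logaddexp(0, eta)) - y @ eta)


class TestRidgeLogistic:
    def test_null_design_gives_logit_of_case_fraction(self):
        X = np.zeros((40, 3))
        y = np.array([1.0] * 10 + [0.0] * 30)
        beta = ridge_logistic(X, y, 1.0 / 40)
        assert beta[0] == pytest.approx(math.log(10 / 30), abs=1e-8)
        np.testing.assert_allclose(beta[1:], 0.0, atol=1e-10)

    def test_huge_penalty_shrinks_slopes_to_zero(self):
        X, y = _logit_data(1, beta=np.array([2.0, -1.0, 0.0, 0.0]))
        beta = ridge_logistic(X, y, 1e8)
        np.testing.assert_allclose(beta[1:], 0.0, atol=1e-6)
        assert beta[0] == pytest.approx(math.log(y.mean() / (1 - y.mean())), abs=1e-4)

    def test_matches_generic_optimizer(self):
        X, y = _logit_data(2, n=40, d=3, beta=np.array([1.0, 0.0, -0.8]))
        lam2 = 0.05
        beta = ridge_logistic(X, y, lam2)
        obj = lambda b: _negll(X, y, b) + 0.5 * lam2 * np.sum(b[1:] ** 2)
        ref = minimize(obj, np.zeros(4), method="BFGS", options={"gtol": 1e-10})
        assert obj(beta) == pytest.approx(ref.fun, abs=1e-6)


class TestAdaptiveRidgeInit:
    def test_well_conditioned_uses_one_over_n(self):
        X, y = _logit_data(3)
        init = adaptive_ridge_init(X, y)
        assert init.lambda2 == pytest.approx(1.0 / len(y))

    def test_duplicate_columns_still_succeed(self):
        X, y = _logit_data(4, d=3)
        X = np.column_stack([X, X[:, 0]])  # exact collinearity
        init = adaptive_ridge_init(X, y)
        assert np.all(np.isfinite(init.beta0))
        assert init.lambda2 > 0

    def test_escalation_sequence_is_powers_of_ten(self, monkeypatch):
        calls = []
        real = stl.ridge_logistic

        def flaky(X, y, lambda2, **kw):
            calls.append(lambda2)
            if len(calls) < 3:
                raise stl._SolveError("forced")
            return real(X, y, lambda2, **kw)

        monkeypatch.setattr(stl, "ridge_logistic", flaky)
        X, y = _logit_data(5)
        init = adaptive_ridge_init(X, y)
        n = len(y)
        np.testing.assert_allclose(calls, [1 / n, 10 / n, 100 / n])
        assert init.lambda2 == pytest.approx(100 / n)

    def test_hard_error_after_cap(self, monkeypatch):
        def always_fail(X, y, lambda2, **kw):
            raise stl._SolveError("forced")

        monkeypatch.setattr(stl, "ridge_logistic", always_fail)
        X, y = _logit_data(6)
        with pytest.raises(RuntimeError, match="pathological"):
            adaptive_ridge_init(X, y)


class TestStWeights:
    def test_lambda_zero_activates_all(self):
        delta, active = st_weights(np.array([0.5, -2.0, 0.0]), 0.0)
        np.testing.assert_array_equal(delta, 0.0)
        assert list(active) == [0, 1, 2]

    def test_lambda_above_all_squares_empties_active_set(self):
        delta, active = st_weights(np.array([0.5, -2.0]), 5.0)
        np.testing.assert_array_equal(delta, 1.0)
        assert active.size == 0

    def test_worked_example(self):
        delta, active = st_weights(np.array([2.0, 0.5]), 1.0)
        np.testing.assert_allclose(delta, [0.25, 1.0])
        assert list(active) == [0]

    def test_zero_initial_coefficient_excluded(self):
        delta, active = st_weights(np.array([0.0, 1.0]), 0.5)
        assert delta[0] == 1.0 and 0 not in active


class TestStFit:
    def test_lambda_zero_reduces_to_ridge(self):
        X, y = _logit_data(7, beta=np.array([1.2, 0.0, -0.6, 0.0]))
        init = adaptive_ridge_init(X, y)
        f = st_fit(X, y, init, 0.0)
        np.testing.assert_allclose(
            np.concatenate([[f.intercept], f.beta]), init.beta0, atol=1e-8
        )

    def test_large_lambda_gives_null_model(self):
        X, y = _logit_data(8)
        init = adaptive_ridge_init(X, y)
        lam = float(np.max(init.beta0[1:] ** 2)) * 2
        f = st_fit(X, y, init, lam)
        assert f.dim == 0
        pbar = y.mean()
        ll0 = len(y) * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))
        assert f.loglik == pytest.approx(ll0, abs=1e-10)

    def test_reported_zeros_are_exact(self):
        X, y = _logit_data(9, beta=np.array([1.5, 0.0, 0.0, -1.0]))
        init = adaptive_ridge_init(X, y)
        lam = float(np.sort(init.beta0[1:] ** 2)[1]) * (1 + 1e-9)
        f = st_fit(X, y, init, lam)
        off = np.setdiff1d(np.arange(4), f.active_set)
        assert off.size > 0
        assert np.all(f.beta[off] == 0.0)

    def test_objective_matches_generic_optimizer(self):
        X, y = _logit_data(10, n=60, d=4, beta=np.array([1.0, -0.5, 0.0, 0.7]))
        init = adaptive_ridge_init(X, y)
        for lam in (0.02, 0.2):
            delta, active = st_weights(init.beta0[1:], lam)
            if active.size == 0:
                continue
            f = st_fit(X, y, init, lam)
            w = init.lambda2 + delta[active] / (1 - delta[active])

            def obj(b):
                full = np.zeros(4)
                full[active] = b[1:]
                return _negll(X, y, np.concatenate([[b[0]], full])) + 0.5 * float(
                    w @ b[1:] ** 2
                )

            ref = minimize(obj, np.zeros(active.size + 1), method="BFGS",
                           options={"gtol": 1e-10})
            mine = obj(np.concatenate([[f.intercept], f.beta[f.active_set]]))
            assert mine == pytest.approx(ref.fun, abs=1e-6)

    def test_nonconvergence_raises_with_partial_state(self):
        X, y = _logit_data(11)
        init = adaptive_ridge_init(X, y)
        with pytest.raises(ConvergenceError):
            st_fit(X, y, init, 1e-6, max_iter=1, tol=1e-14)


class TestLambdaPath:
    def test_breakpoints_visit_every_active_set_size(self):
        init = RidgeInit(beta0=np.array([0.1, 2.0, -1.0, 0.5]), lambda2=0.01)
        path = lambda_path(init)
        assert len(path) == 4
        sizes = [st_weights(init.beta0[1:], lam)[1].size for lam in path]
        assert sizes == [3, 2, 1, 0]

    def test_duplicate_magnitudes_collapse(self):
        init = RidgeInit(beta0=np.array([0.0, 1.0, -1.0, 0.5]), lambda2=0.01)
        path = lambda_path(init)
        assert len(path) == 3  # 0, 0.25+, 1.0+

    def test_matches_dense_grid_scan(self):
        X, y = _logit_data(12, d=5, beta=np.array([1.0, -0.6, 0.3, 0.0, 0.9]))
        init = adaptive_ridge_init(X, y)
        path_sets = {
            tuple(st_weights(init.beta0[1:], lam)[1]) for lam in lambda_path(init)
        }
        grid = np.linspace(0, float(np.max(init.beta0[1:] ** 2)) * 1.1, 5000)
        grid_sets = {tuple(st_weights(init.beta0[1:], lam)[1]) for lam in grid}
        assert path_sets == grid_sets


class TestEbic:
    def test_gamma_zero_is_bic(self):
        X, y = _logit_data(13, beta=np.array([1.5, 0.0, 0.0, 0.0]))
        init = adaptive_ridge_init(X, y)
        f = st_fit(X, y, init, 0.0)
        cfg = EbicConfig(gamma=0.0, p_full=10**6, n=len(y))
        assert ebic(f, cfg) == pytest.approx(
            -2 * f.loglik + math.log(len(y)) * f.dim
        )

    def test_zero_dimension_ignores_gamma(self):
        X, y = _logit_data(14)
        init = adaptive_ridge_init(X, y)
        f = st_fit(X, y, init, float(np.max(init.beta0[1:] ** 2)) * 2)
        v0 = ebic(f, EbicConfig(gamma=0.0, p_full=100, n=len(y)))
        v1 = ebic(f, EbicConfig(gamma=1.0, p_full=100, n=len(y)))
        assert v0 == v1 == pytest.approx(-2 * f.loglik)

    def test_formula_worked_example(self):
        f = stl.StFit(
            beta=np.array([0.3, 0.2]), intercept=0.0,
            active_set=np.array([0, 1]), lam=0.0, lambda2=0.01,
            loglik=-600.0, dim=2, delta=np.zeros(2),
        )
        v = ebic(f, EbicConfig(gamma=0.0, p_full=4498500, n=1000))
        assert v == pytest.approx(1200 + 2 * math.log(1000), abs=1e-10)

    def test_gamma_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            EbicConfig(gamma=1.5, p_full=10, n=10)


class TestSelectModel:
    def test_pure_noise_at_gamma_one_selects_nothing(self):
        rng = np.random.default_rng(15)
        n = 500
        X = (rng.random((n, 6)) < 0.3).astype(float)
        y = np.array([1.0] * 250 + [0.0] * 250)
        fit = select_model(X, y, EbicConfig(gamma=1.0, p_full=10**6, n=n))
        assert fit.dim == 0

    def test_planted_strong_predictor_selected(self):
        rng = np.random.default_rng(16)
        n = 1000
        X = (rng.random((n, 5)) < 0.3).astype(float)
        eta = -1.0 + math.log(4.0) * X[:, 2]  # OR = 4 on column 2
        y = (rng.random(n) < expit(eta)).astype(float)
        fit = select_model(X, y, EbicConfig(gamma=0.5, p_full=10**6, n=n))
        assert 2 in fit.active_set

    def test_dimension_monotone_in_gamma(self):
        rng = np.random.default_rng(17)
        n = 300
        X = (rng.random((n, 8)) < 0.4).astype(float)
        eta = -0.5 + 0.8 * X[:, 0] - 0.6 * X[:, 3]
        y = (rng.random(n) < expit(eta)).astype(float)
        init = adaptive_ridge_init(X, y)
        fits = fit_path(X, y, init)
        dims = [
            select_from_path(fits, EbicConfig(gamma=g, p_full=10**5, n=n)).dim
            for g in np.arange(0, 1.01, 0.1)
        ]
        assert all(a >= b for a, b in zip(dims, dims[1:]))
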