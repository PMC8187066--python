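"""Smoothed-L0 machinery: surrogate, projections, adaptive damping, recovery behavior."""

import itertools

import numpy as np
import pytest
import scipy.linalg

import pasl0 as p
from pasl0.solvers import (
    GramSolver,
    NumericalRankError,
    SL0,
    ReSL0,
    _gradient_step,
)
from .conftest import random_sparse_instance


class TestSurrogate:
    def test_value_at_zero_is_n(self):
        assert p.smoothed_l0_value(np.zeros(17), sigma=3.0) == pytest.approx(17.0)

    def test_direct_substitution(self):
        # theta = (sigma, 0): F = e^-1 + 1
        assert p.smoothed_l0_value(np.array([2.0, 0.0]), 2.0) == pytest.approx(
            np.exp(-1) + 1, abs=1e-12
        )

    def test_counts_support_in_small_sigma_limit(self):
        theta = np.array([1.0, 0.0, -2.0, 0.0])
        f = p.smoothed_l0_value(theta, 1e-4)
        assert abs((theta.size - f) - 2.0) < 1e-12

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(0)
        theta = rng.standard_normal(20)
        sigma = 0.7
        g = p.smoothed_l0_gradient(theta, sigma)
        h = 1e-6
        for i in [0, 5, 13]:
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            fd = (p.smoothed_l0_value(tp, sigma) - p.smoothed_l0_value(tm, sigma)) / (2 * h)
            assert abs(g[i] - fd) < 1e-6

    def test_gradient_fixed_point_and_substitution(self):
        assert np.all(p.smoothed_l0_gradient(np.zeros(5), 1.0) == 0)
        sigma = 0.3
        g = p.smoothed_l0_gradient(np.array([sigma]), sigma)
        assert g[0] == pytest.approx(-2 / sigma * np.exp(-1), rel=1e-12)

    @pytest.mark.parametrize("fn", [p.smoothed_l0_value, p.smoothed_l0_gradient])
    def test_nonpositive_sigma_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(np.ones(3), 0.0)


class TestEqualityProjection:
    def test_feasible_point_unchanged(self):
        rng = np.random.default_rng(1)
        A = rng.standard_normal((6, 12))
        theta = rng.standard_normal(12)
        y = A @ theta
        out = p.equality_projection(theta, A, y)
        np.testing.assert_allclose(out, theta, atol=1e-10)

    def test_matches_constrained_least_squares_kkt_oracle(self):
        """The projection is the Euclidean-nearest feasible point (KKT system)."""
        rng = np.random.default_rng(2)
        A = rng.standard_normal((6, 12))
        theta = rng.standard_normal(12)
        y = rng.standard_normal(6)
        out = p.equality_projection(theta, A, y)
        # KKT: [[I, A^T], [A, 0]] [x; nu] = [theta; y]
        kkt = np.block([[np.eye(12), A.T], [A, np.zeros((6, 6))]])
        sol = np.linalg.solve(kkt, np.concatenate([theta, y]))
        np.testing.assert_allclose(out, sol[:12], atol=1e-9)
        assert np.linalg.norm(A @ out - y) / np.linalg.norm(y) <= 1e-8

    def test_orthonormal_rows_closed_form(self):
        rng = np.random.default_rng(3)
        Q = np.linalg.qr(rng.standard_normal((12, 6)))[0].T  # 6x12, QQ^T = I
        theta = rng.standard_normal(12)
        y = rng.standard_normal(6)
        out = p.equality_projection(theta, Q, y)
        np.testing.assert_allclose(out, theta - Q.T @ (Q @ theta - y), atol=1e-10)

    def test_rank_deficient_system_raises(self):
        # an overdetermined system makes A A^T structurally singular
        rng = np.random.default_rng(4)
        A = rng.standard_normal((13, 12))
        with pytest.raises(NumericalRankError):
            p.equality_projection(rng.standard_normal(12), A, rng.standard_normal(13))


class TestRegularizedProjection:
    def test_two_independent_oracles(self):
        """Matches both the shifted-Gram linear solve and the Tikhonov
        normal-equations solution of argmin ||t - theta||^2 + lam ||A t - y||^2."""
        rng = np.random.default_rng(5)
        A = rng.standard_normal((6, 12))
        theta = rng.standard_normal(12)
        y = rng.standard_normal(6)
        lam = 3.7
        out = p.regularized_projection(theta, A, y, lam)
        # oracle 1: z solves (A A^T + I/lam) z = A theta - y
        z = np.linalg.solve(A @ A.T + np.eye(6) / lam, A @ theta - y)
        np.testing.assert_allclose(out, theta - A.T @ z, atol=1e-9)
        # oracle 2: dense normal equations in the primal
        t = np.linalg.solve(np.eye(12) + lam * A.T @ A, theta + lam * A.T @ y)
        np.testing.assert_allclose(out, t, atol=1e-9)

    def test_large_lambda_limit_is_equality_projection(self):
        rng = np.random.default_rng(6)
        A = rng.standard_normal((6, 12))
        theta = rng.standard_normal(12)
        y = rng.standard_normal(6)
        reg = p.regularized_projection(theta, A, y, 1e12)
        eq = p.equality_projection(theta, A, y)
        np.testing.assert_allclose(reg, eq, atol=1e-8)

    def test_orthonormal_rows_analytic_form(self):
        rng = np.random.default_rng(7)
        Q = np.linalg.qr(rng.standard_normal((12, 6)))[0].T
        theta = rng.standard_normal(12)
        y = rng.standard_normal(6)
        lam = 2.5
        out = p.regularized_projection(theta, Q, y, lam)
        expected = theta - (1 / (1 + 1 / lam)) * Q.T @ (Q @ theta - y)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_never_increases_residual(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((10, 25))
        y = rng.standard_normal(10)
        for lam in [1e-6, 1.0, 1e6]:
            theta = rng.standard_normal(25)
            out = p.regularized_projection(theta, A, y, lam)
            assert np.linalg.norm(A @ out - y) <= np.linalg.norm(A @ theta - y) + 1e-12

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            p.regularized_projection(np.ones(4), np.eye(4), np.ones(4), 0.0)


class TestAdaptiveLambda:
    def test_zero_numerator_gives_floor(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((4, 8))
        theta = rng.standard_normal(8)
        lam = p.adaptive_lambda(theta, theta, A, rng.standard_normal(4), floor=1e-9, cap=1e9)
        assert lam == 1e-9

    def test_zero_residual_gives_cap(self):
        rng = np.random.default_rng(10)
        A = rng.standard_normal((4, 8))
        theta = rng.standard_normal(8)
        y = A @ theta
        lam = p.adaptive_lambda(theta + 0.1, theta, A, y, floor=1e-9, cap=1e9)
        assert lam == 1e9

    def test_hand_evaluated_ratio(self):
        A = np.arange(32.0).reshape(4, 8) / 10 + np.eye(4, 8)
        theta_prev = np.linspace(-1, 1, 8)
        theta_grad = theta_prev + 0.05 * np.arange(8)
        y = np.array([0.3, -0.2, 0.1, 0.4])
        num = np.sum((theta_grad - theta_prev) ** 2)
        den = np.sum((A.T @ (A @ theta_prev - y)) ** 2)
        lam = p.adaptive_lambda(theta_grad, theta_prev, A, y)
        assert lam == pytest.approx(num / den, rel=1e-12)


def exhaustive_l0_oracle(A, y, k_max, tol=1e-8):
    """Smallest support solving y = A theta exactly, by brute enumeration."""
    n = A.shape[1]
    for k in range(k_max + 1):
        for support in itertools.combinations(range(n), k):
            if k == 0:
                if np.linalg.norm(y) < tol:
                    return support
                continue
            sub = A[:, list(support)]
            coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.linalg.norm(sub @ coef - y) < tol * max(1, np.linalg.norm(y)):
                return support
    return None


class TestSL0Recovery:
    def test_zero_measurements_give_zero_solution(self):
        rng = np.random.default_rng(11)
        A = rng.standard_normal((8, 16))
        res = p.sl0_solve(A, np.zeros(8))
        assert np.all(res.theta_hat == 0)
        assert res.converged and res.n_outer == 1

    def test_exact_recovery_gaussian_instance(self):
        rng = np.random.default_rng(12)
        A, theta, y = random_sparse_instance(rng, n=64, m=32, k=4)
        res = p.sl0_solve(A, y)
        # recovery down to the sigma-schedule floor (sigma_min_ratio * sigma_0)
        assert np.linalg.norm(res.theta_hat - theta) / np.linalg.norm(theta) < 1e-3
        # final iterate is feasible
        assert np.linalg.norm(A @ res.theta_hat - y) / np.linalg.norm(y) <= 1e-6

    def test_support_matches_exhaustive_l0_search(self):
        rng = np.random.default_rng(13)
        A, theta, y = random_sparse_instance(rng, n=12, m=8, k=2)
        res = p.sl0_solve(A, y)
        oracle_support = exhaustive_l0_oracle(A, y, k_max=2)
        got = set(np.where(np.abs(res.theta_hat) > 0.01 * np.abs(res.theta_hat).max())[0])
        assert got == set(oracle_support)

    def test_sigma_schedule_geometric_and_traces_aligned(self):
        rng = np.random.default_rng(14)
        A, theta, y = random_sparse_instance(rng)
        res = p.sl0_solve(A, y)
        s = res.sigma_trace
        assert np.all(np.diff(s) < 0)
        np.testing.assert_allclose(s[1:] / s[:-1], 0.8, rtol=1e-12)
        assert len(s) == res.n_outer == len(res.residual_trace)

    def test_surrogate_counts_support_of_final_iterate(self):
        rng = np.random.default_rng(15)
        A, theta, y = random_sparse_instance(rng)
        res = p.sl0_solve(A, y)
        sigma_final = res.sigma_trace[-1]
        l0 = np.count_nonzero(np.abs(res.theta_hat) > 10 * sigma_final)
        approx = res.theta_hat.size - p.smoothed_l0_value(res.theta_hat, sigma_final)
        assert abs(approx - l0) < 0.5

    def test_overdetermined_system_raises(self):
        rng = np.random.default_rng(16)
        A = rng.standard_normal((20, 10))
        with pytest.raises(NumericalRankError):
            p.sl0_solve(A, rng.standard_normal(20))

    def test_phase_transition_recovery_rate(self):
        """Noiseless recovery succeeds for most draws inside the recovery
        region (M = 6k at N = 128; undersampling ratios here sit near the
        classical l1 phase-transition curve, so rates below 1 are expected)."""
        floors = {4: 70, 8: 80}
        for k, floor in floors.items():
            successes = 0
            for seed in range(100):
                rng = np.random.default_rng(1000 + seed)
                A, theta, y = random_sparse_instance(rng, n=128, m=6 * k, k=k)
                res = p.sl0_solve(A, y)
                ok = np.linalg.norm(res.theta_hat - theta) < 1e-3 * np.linalg.norm(theta)
                successes += ok
            assert successes > floor


class TestReSL0:
    def test_zero_measurements(self):
        rng = np.random.default_rng(17)
        A = rng.standard_normal((8, 16))
        res = p.resl0_solve(A, np.zeros(8))
        assert np.all(res.theta_hat == 0)
        assert res.converged and res.n_outer == 1

    def test_noiseless_matches_sl0_recovery(self):
        rng = np.random.default_rng(18)
        A, theta, y = random_sparse_instance(rng, n=64, m=32, k=4)
        res = p.resl0_solve(A, y)
        assert np.linalg.norm(res.theta_hat - theta) / np.linalg.norm(theta) < 1e-3

    def test_lambda_trace_recorded_and_clipped(self):
        rng = np.random.default_rng(19)
        A, theta, y = random_sparse_instance(rng)
        y = y + 0.01 * rng.standard_normal(y.size)
        cfg = p.SolverConfig(lambda_floor=1e-6, lambda_cap=1e6)
        res = p.resl0_solve(A, y, cfg)
        assert res.lambda_trace is not None
        assert len(res.lambda_trace) == res.n_outer
        assert np.all(res.lambda_trace >= 1e-6) and np.all(res.lambda_trace <= 1e6)

    def test_forced_large_lambda_reproduces_sl0_iterates(self):
        """With the damping weight pinned at 1e12 the regularized projection
        collapses to the exact one, so both solvers follow the same path."""
        rng = np.random.default_rng(20)
        A, theta, y = random_sparse_instance(rng, n=32, m=16, k=3)
        cfg_fixed = p.SolverConfig(lambda_floor=1e12, lambda_cap=1e12)
        r_resl0 = p.resl0_solve(A, y, cfg_fixed, store_history=True)
        r_sl0 = p.sl0_solve(A, y, store_history=True)
        assert r_resl0.n_outer == r_sl0.n_outer
        for h1, h2 in zip(r_resl0.history, r_sl0.history):
            np.testing.assert_allclose(h1, h2, atol=1e-6)

    def test_noise_robustness_over_many_seeds(self):
        """Median recovery error under 20 dB noise: tolerance-aware ReSL0 < SL0."""
        rng = np.random.default_rng(21)
        A, theta, y = random_sparse_instance(rng, n=64, m=32, k=4)
        noise_norm = np.linalg.norm(y) * 10 ** (-20 / 20)
        cfg = p.SolverConfig(error_tolerance=noise_norm)
        errs_sl0, errs_resl0 = [], []
        for seed in range(50):
            nrng = np.random.default_rng(5000 + seed)
            e = nrng.standard_normal(32)
            e *= noise_norm / np.linalg.norm(e)
            yn = y + e
            errs_sl0.append(np.linalg.norm(p.sl0_solve(A, yn).theta_hat - theta))
            errs_resl0.append(np.linalg.norm(p.resl0_solve(A, yn, cfg).theta_hat - theta))
        assert np.median(errs_resl0) <= np.median(errs_sl0)

    def test_non_finite_y_rejected(self):
        rng = np.random.default_rng(22)
        A = rng.standard_normal((8, 16))
        y = rng.standard_normal(8)
        y[3] = np.nan
        with pytest.raises(ValueError):
            p.resl0_solve(A, y)


class TestEstimatorProtocol:
    def test_get_set_params_round_trip(self):
        est = ReSL0(rho=0.9, lambda_cap=1e9)
        params = est.get_params()
        assert params["rho"] == 0.9 and params["lambda_cap"] == 1e9
        est.set_params(mu=1.5)
        assert est.mu == 1.5

    def test_predict_applies_operator(self):
        rng = np.random.default_rng(23)
        A, theta, y = random_sparse_instance(rng)
        est = SL0().fit(A, y)
        np.testing.assert_allclose(est.predict(A), A @ est.coef_, rtol=1e-12)

    def test_invalid_hyperparameters_rejected_at_fit(self):
        rng = np.random.default_rng(24)
        A, theta, y = random_sparse_instance(rng)
        for bad in [dict(rho=0.4), dict(rho=1.0), dict(mu=0.0), dict(inner_iters=0),
                    dict(stop_tol=0.0)]:
            with pytest.raises(ValueError):
                SL0(**bad).fit(A, y)
        with pytest.raises(ValueError):
            ReSL0(lambda_floor=0.0).fit(A, y)

    def test_solver_config_validation(self):
        with pytest.raises(ValueError):
            p.SolverConfig(rho=0.3)
        with pytest.raises(ValueError):
            p.SolverConfig(stop_tol=1.5)


class TestGramSolverNumerics:
    def test_shifted_solve_matches_direct(self):
        rng = np.random.default_rng(25)
        B = rng.standard_normal((6, 6))
        G = B @ B.T
        gs = GramSolver(G)
        v = rng.standard_normal(6)
        for shift in [0.0, 0.5, 10.0]:
            direct = np.linalg.solve(G + shift * np.eye(6), v)
            np.testing.assert_allclose(gs.solve(v, shift), direct, rtol=1e-8)

    def test_gradient_step_formula(self):
        theta = np.array([0.0, 0.5, -2.0])
        sigma, mu = 0.5, 1.0
        expected = theta + mu * sigma**2 * p.smoothed_l0_gradient(theta, sigma)
        np.testing.assert_allclose(_gradient_step(theta, sigma, mu), expected, rtol=1e-12)
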