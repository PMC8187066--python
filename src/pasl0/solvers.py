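"""Smoothed-L0 sparse recovery: the SL0 baseline and the regularized ReSL0 solver.

Both solvers seek the sparsest coefficient vector theta consistent with an
underdetermined linear system y = A @ theta by maximising the Gaussian
surrogate

    F_sigma(theta) = sum_i exp(-theta_i**2 / sigma**2),

for which N - F_sigma(theta) -> ||theta||_0 as sigma -> 0. A geometrically
decreasing sigma schedule (graduated non-convexity) avoids bad local maxima:
sigma_0 = 4 * max|theta_0| with theta_0 the minimum-norm solution, then
sigma_j = rho * sigma_{j-1}. For each sigma an inner loop takes small
gradient-ascent steps on F_sigma and pulls the iterate back towards the data:

* SL0 projects exactly onto the affine feasible set {A theta = y}:
      theta <- theta - A.T (A A.T)^{-1} (A theta - y).
* ReSL0 tolerates measurement error by replacing the exact projection with a
  Tikhonov-damped one,
      theta <- theta - A.T (A A.T + (1/lambda) I)^{-1} (A theta - y),
  the Lagrange form of the nearest point under the residual bound
  ||A theta - y|| <= delta; the multiplier lambda is resolved per outer
  iteration so the post-projection residual meets delta (see :class:`ReSL0`).
  Large lambda recovers the exact projection (the delta = 0 / noiseless
  limit); a finite lambda refuses to chase measurement noise below the
  tolerance. The standalone :func:`adaptive_lambda` implements the classical
  sparsity-step-to-misfit-gradient ratio for the damping weight.

The estimators follow the scikit-learn protocol (``fit(A, y)`` storing
``coef_``), so they compose with sklearn model selection; ``sl0_solve`` and
``resl0_solve`` are functional wrappers returning a ``SolverResult``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .sparsity import SensingOperator, as_operator

__all__ = [
    "NumericalRankError",
    "GramSolver",
    "smoothed_l0_value",
    "smoothed_l0_gradient",
    "equality_projection",
    "regularized_projection",
    "adaptive_lambda",
    "SolverConfig",
    "SolverResult",
    "SL0",
    "ReSL0",
    "sl0_solve",
    "resl0_solve",
]


class NumericalRankError(np.linalg.LinAlgError):
    """The Gram matrix A @ A.T is numerically rank deficient."""


class GramSolver:
    """Shifted solves (G + shift * I)^{-1} v via one symmetric eigendecomposition.

    The eigendecomposition is computed once and reused for every shift, which
    is what makes the per-outer-iteration lambda of ReSL0 affordable: each
    projection costs O(M^2) instead of a fresh O(M^3) factorization.

    Frequency-domain tomography Gram matrices are legitimately very
    ill-conditioned (relative eigenvalues down to ~1e-15), so rank deficiency
    is detected structurally (more measurements than unknowns when ``n_cols``
    is known) plus a near-machine-zero eigenvalue test, mirroring standard
    pseudo-inverse truncation rather than a conservative condition bound.
    """

    #: relative eigenvalue cutoff below which G counts as rank deficient
    RCOND = 1e-16

    def __init__(self, G: np.ndarray, n_cols: int | None = None) -> None:
        G = np.asarray(G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("G must be square")
        self.eigvals, self.eigvecs = scipy.linalg.eigh(G)
        self._scale = max(self.eigvals.max(), 0.0)
        self._structurally_deficient = n_cols is not None and G.shape[0] > n_cols

    @property
    def full_rank(self) -> bool:
        if self._structurally_deficient:
            return False
        return self.eigvals.min() > self.RCOND * self._scale

    def solve(self, v: np.ndarray, shift: float = 0.0) -> np.ndarray:
        """(G + shift I)^{-1} v; shift=0 requires full numerical rank.

        When G is numerically rank deficient, eigendirections below the noise
        floor of the eigendecomposition are truncated even for shifted solves:
        those directions carry no information about the data, only rounding
        noise, and a small shift would amplify it catastrophically.
        """
        if shift == 0.0 and not self.full_rank:
            raise NumericalRankError(
                "A A^T is numerically rank deficient; the exact feasibility "
                "projection is undefined (is the system overdetermined?)"
            )
        w = self.eigvecs.T @ np.asarray(v, dtype=float).ravel()
        if self.full_rank:
            return self.eigvecs @ (w / (self.eigvals + shift))
        keep = self.eigvals > self.PINV_RCOND * self._scale
        out = np.zeros_like(w)
        out[keep] = w[keep] / (self.eigvals[keep] + shift)
        return self.eigvecs @ out

    #: truncation level for pseudo-inverse solves; eigenvalues of G below this
    #: relative level are indistinguishable from the eigensolver's own noise
    PINV_RCOND = 1e-14

    def pinv_solve(self, v: np.ndarray, rcond: float | None = None) -> np.ndarray:
        """Moore-Penrose solve G^+ v (small eigenvalues truncated)."""
        rcond = self.PINV_RCOND if rcond is None else rcond
        w = self.eigvecs.T @ np.asarray(v, dtype=float).ravel()
        keep = self.eigvals > rcond * self._scale
        out = np.zeros_like(w)
        out[keep] = w[keep] / self.eigvals[keep]
        return self.eigvecs @ out

    def feasibility_solve(self, v: np.ndarray) -> np.ndarray:
        """(A A^T)^{-1} v when well posed, else the pseudo-inverse solve.

        Frequency-band physics bounds the number of independent measurements
        (space-bandwidth product), so tomographic Gram matrices are routinely
        rank deficient even when the row count is below N; truncating the
        null modes is the standard pseudo-inverse treatment and leaves the
        projection exact on the numerically sensed subspace.
        """
        if self.full_rank:
            return self.solve(v, 0.0)
        return self.pinv_solve(v)


# -- surrogate ------------------------------------------------------------


def smoothed_l0_value(theta: np.ndarray, sigma: float) -> float:
    """F_sigma(theta) = sum_i exp(-theta_i^2 / sigma^2), in (0, N]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    theta = np.asarray(theta, dtype=float)
    return float(np.exp(-((theta / sigma) ** 2)).sum())


def smoothed_l0_gradient(theta: np.ndarray, sigma: float) -> np.ndarray:
    """Gradient of F_sigma: component i is (-2 theta_i / sigma^2) exp(-theta_i^2/sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    theta = np.asarray(theta, dtype=float)
    return (-2.0 * theta / sigma**2) * np.exp(-((theta / sigma) ** 2))


def _gradient_step(theta: np.ndarray, sigma: float, mu: float) -> np.ndarray:
    """One ascent step theta + mu * sigma^2 * grad F_sigma."""
    return theta - 2.0 * mu * theta * np.exp(-((theta / sigma) ** 2))


# -- projections ----------------------------------------------------------


def equality_projection(theta, A, y, solver: GramSolver | None = None) -> np.ndarray:
    """Euclidean projection onto the affine feasible set {theta : A theta = y}.

    Returns theta - A.T (A A.T)^{-1} (A theta - y); raises
    ``NumericalRankError`` when A A.T is numerically singular.
    """
    op = as_operator(A)
    theta = np.asarray(theta, dtype=float).ravel()
    if solver is None:
        solver = op.gram_solver()
    r = op.matvec(theta) - np.asarray(y, dtype=float).ravel()
    return theta - op.rmatvec(solver.solve(r, 0.0))


def regularized_projection(theta, A, y, lam: float, solver: GramSolver | None = None) -> np.ndarray:
    """Tikhonov-damped feasibility step theta - A.T (A A.T + I/lam)^{-1} (A theta - y).

    Solves argmin ||theta_p - theta||^2 + lam * ||A theta_p - y||^2, i.e. the
    Lagrange form of the nearest-point problem under a residual tolerance.
    Never increases the residual; as lam -> inf it tends to the exact
    equality projection.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    op = as_operator(A)
    theta = np.asarray(theta, dtype=float).ravel()
    if solver is None:
        solver = op.gram_solver()
    r = op.matvec(theta) - np.asarray(y, dtype=float).ravel()
    return theta - op.rmatvec(solver.solve(r, 1.0 / lam))


def adaptive_lambda(
    theta_grad_step: np.ndarray,
    theta_prev: np.ndarray,
    A,
    y,
    floor: float = 1e-12,
    cap: float = 1e12,
) -> float:
    """Adaptive damping weight lambda for one outer iteration of ReSL0.

    lambda = ||theta_grad - theta_prev||^2 / ||A.T (A theta_prev - y)||^2,
    clipped to [floor, cap]. Degenerate cases: a zero denominator with a
    nonzero numerator (the iterate is already feasible, no damping needed)
    returns ``cap``; both zero returns ``floor``.
    """
    if floor <= 0 or cap < floor:
        raise ValueError("need 0 < floor <= cap")
    op = as_operator(A)
    tg = np.asarray(theta_grad_step, dtype=float).ravel()
    tp = np.asarray(theta_prev, dtype=float).ravel()
    if tg.size != tp.size:
        raise ValueError("theta vectors must have equal length")
    num = float(np.sum((tg - tp) ** 2))
    r = op.matvec(tp) - np.asarray(y, dtype=float).ravel()
    den = float(np.sum(op.rmatvec(r) ** 2))
    if den == 0.0:
        return cap if num > 0.0 else floor
    return float(np.clip(num / den, floor, cap))


# -- configuration / result containers ------------------------------------


@dataclass
class SolverConfig:
    """Shared sigma-schedule and stopping parameters for SL0/ReSL0.

    Attributes
    ----------
    rho : float
        Geometric decay factor of the sigma schedule, in (0.5, 1).
    mu : float
        Inner gradient step size (the update is theta + mu sigma^2 grad F).
    inner_iters : int
        Gradient-plus-projection steps per sigma value.
    sigma_min_ratio : float
        Schedule floor: stop once sigma < sigma_min_ratio * sigma_0.
    stop_tol : float
        Relative image-change stopping threshold ||X_k+1 - X_k|| / ||X_k||.
    max_outer : int
        Hard cap on outer iterations; exceeding it flags converged=False.
    error_tolerance : float
        Residual tolerance delta of the noise-aware data constraint
        ||A theta - y|| <= delta (ReSL0 only; 0 reduces to the equality
        constraint). Typically set to the measurement-noise norm.
    lambda_floor, lambda_cap : float
        Clipping bounds for the adaptive lambda (ReSL0 only).
    """

    rho: float = 0.8
    mu: float = 1.0
    inner_iters: int = 3
    sigma_min_ratio: float = 1e-4
    stop_tol: float = 0.005
    max_outer: int = 200
    error_tolerance: float = 0.0
    lambda_floor: float = 1e-12
    lambda_cap: float = 1e12

    def __post_init__(self) -> None:
        if not 0.5 < self.rho < 1.0:
            raise ValueError("rho must lie in (0.5, 1)")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")
        if not 0 < self.stop_tol < 1:
            raise ValueError("stop_tol must lie in (0, 1)")
        if not 0 < self.sigma_min_ratio < 1:
            raise ValueError("sigma_min_ratio must lie in (0, 1)")
        if self.lambda_floor <= 0 or self.lambda_cap < self.lambda_floor:
            raise ValueError("need 0 < lambda_floor <= lambda_cap")


@dataclass
class SolverResult:
    """Outcome of one smoothed-L0 reconstruction."""

    theta_hat: np.ndarray
    image_hat: np.ndarray | None
    sigma_trace: np.ndarray
    lambda_trace: np.ndarray | None
    residual_trace: np.ndarray
    n_outer: int
    converged: bool
    history: list[np.ndarray] = field(default_factory=list)

    def save(self, directory) -> None:
        """Serialize: per-iteration traces as CSV, coefficient/image arrays as .npy."""
        import pandas as pd
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        traces = {"outer_iteration": np.arange(self.n_outer),
                  "sigma": self.sigma_trace,
                  "residual": self.residual_trace}
        if self.lambda_trace is not None:
            traces["lambda"] = self.lambda_trace
        pd.DataFrame(traces).to_csv(directory / "traces.csv", index=False)
        np.save(directory / "theta_hat.npy", self.theta_hat)
        if self.image_hat is not None:
            np.save(directory / "image_hat.npy", self.image_hat)


# -- estimators -----------------------------------------------------------


class _SmoothedL0Base(RegressorMixin, BaseEstimator):
    """Shared machinery of the SL0 family; not used directly."""

    def __init__(
        self,
        rho: float = 0.8,
        mu: float = 1.0,
        inner_iters: int = 3,
        sigma_min_ratio: float = 1e-4,
        stop_tol: float = 0.005,
        max_outer: int = 200,
        store_history: bool = False,
        verbose: bool = False,
    ) -> None:
        self.rho = rho
        self.mu = mu
        self.inner_iters = inner_iters
        self.sigma_min_ratio = sigma_min_ratio
        self.stop_tol = stop_tol
        self.max_outer = max_outer
        self.store_history = store_history
        self.verbose = verbose

    # subclass hooks ------------------------------------------------------
    def _initial_theta(self, op, y, solver):
        raise NotImplementedError

    def _outer_setup(self, op, y, solver, theta, sigma):
        """Return per-outer-iteration state (e.g. lambda); None for SL0."""
        return None

    def _project(self, op, y, solver, theta, state):
        raise NotImplementedError

    def _validate(self) -> None:
        if not 0.5 < self.rho < 1.0:
            raise ValueError("rho must lie in (0.5, 1)")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.inner_iters < 1:
            raise ValueError("inner_iters must be >= 1")
        if not 0 < self.stop_tol < 1:
            raise ValueError("stop_tol must lie in (0, 1)")

    # fitting -------------------------------------------------------------
    def fit(self, X, y):
        """Recover the sparse coefficient vector from measurements.

        Parameters
        ----------
        X : (m, n) array or sensing operator
            The sensing operator A acting on coefficient vectors.
        y : (m,) array
            Measurement vector.
        """
        self._validate()
        op = as_operator(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != op.shape[0]:
            raise ValueError(f"y has length {y.size}, operator expects {op.shape[0]}")
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")

        solver = op.gram_solver()
        theta = self._initial_theta(op, y, solver)

        sigma0 = 4.0 * float(np.max(np.abs(theta))) if theta.size else 0.0
        sigma_trace: list[float] = []
        lambda_trace: list[float] = []
        residual_trace: list[float] = []
        history: list[np.ndarray] = []
        converged = False
        n_outer = 0

        if sigma0 == 0.0:  # y = 0 (or A = 0): the zero vector is the answer
            theta = np.zeros(op.shape[1])
            sigma_trace.append(0.0)
            residual_trace.append(float(np.linalg.norm(op.matvec(theta) - y)))
            converged = True
            n_outer = 1
        else:
            sigma = sigma0
            # The relative-change stop compares iterates one tenfold sigma
            # reduction apart. Checking adjacent outer iterates instead would
            # make the test depend on the schedule granularity (a finer rho
            # shrinks per-step changes without the solution being anywhere
            # near converged) and fire on the transient plateaus between
            # coefficient-collapse events.
            window = max(1, int(np.ceil(np.log(10.0) / -np.log(self.rho))))
            recent: list[np.ndarray] = [theta.copy()]
            for _ in range(self.max_outer):
                n_outer += 1
                state = self._outer_setup(op, y, solver, theta, sigma)
                for _ in range(self.inner_iters):
                    theta = _gradient_step(theta, sigma, self.mu)
                    theta = self._project(op, y, solver, theta, state)

                sigma_trace.append(sigma)
                if state is not None:
                    lambda_trace.append(float(state))
                residual_trace.append(float(np.linalg.norm(op.matvec(theta) - y)))
                if self.store_history:
                    history.append(theta.copy())
                if self.verbose:
                    lam_txt = "" if state is None else f" lambda={state:.3e}"
                    print(
                        f"outer {n_outer:3d}  sigma={sigma:.4e}"
                        f"{lam_txt}  residual={residual_trace[-1]:.4e}"
                    )

                recent.append(theta.copy())
                if len(recent) > window + 1:
                    recent.pop(0)
                ref = recent[0]
                ref_norm = float(np.linalg.norm(ref))
                # only meaningful once sigma is inside the coefficient range:
                # above max|theta| the gradient step is a near-uniform scaling
                # that the projection undoes, so the iterate is stationary for
                # the wrong reason
                engaged = sigma < float(np.max(np.abs(theta))) if theta.any() else True
                if (
                    engaged
                    and len(recent) == window + 1
                    and ref_norm > 0
                    and float(np.linalg.norm(theta - ref)) / ref_norm < self.stop_tol
                ):
                    converged = True
                    break
                if sigma * self.rho < self.sigma_min_ratio * sigma0:
                    converged = True
                    break
                sigma *= self.rho

        self.coef_ = theta
        self.n_iter_ = n_outer
        self.sigma0_ = sigma0
        self.sigma_trace_ = np.asarray(sigma_trace)
        self.lambda_trace_ = np.asarray(lambda_trace) if lambda_trace else None
        self.residual_trace_ = np.asarray(residual_trace)
        self.converged_ = converged
        self.history_ = history
        self.operator_ = op
        return self

    def predict(self, X):
        """Apply the sensing operator to the recovered coefficients."""
        return as_operator(X).matvec(self.coef_)

    def image(self) -> np.ndarray | None:
        """Synthesized reconstruction, when fitted on a wavelet sensing operator."""
        if isinstance(self.operator_, SensingOperator):
            return self.operator_.image_from_coefficients(self.coef_)
        return None


class SL0(_SmoothedL0Base):
    """Baseline smoothed-L0 solver with exact equality-constraint projection.

    Solves min ||theta||_0 s.t. y = A theta via graduated non-convexity;
    every inner gradient step is followed by the Euclidean projection onto
    the feasible affine set, so the final iterate satisfies the data exactly.
    Requires A A.T to be invertible (at most as many measurements as
    unknowns).
    """

    def _initial_theta(self, op, y, solver):
        if solver._structurally_deficient:
            raise NumericalRankError(
                "SL0 requires at most as many measurements as unknowns "
                "(A A^T is structurally singular for an overdetermined system)"
            )
        return op.rmatvec(solver.feasibility_solve(y))  # minimum-norm solution

    def _project(self, op, y, solver, theta, state):
        return theta - op.rmatvec(solver.feasibility_solve(op.matvec(theta) - y))


class ReSL0(_SmoothedL0Base):
    """Error-tolerant smoothed-L0 solver with a residual-constrained projection.

    The data constraint is the inequality ||A theta - y|| <= error_tolerance
    (delta). Each inner pull-back solves the nearest-point problem

        min ||theta_p - theta||  s.t.  ||A theta_p - y|| <= delta,

    whose Lagrange form is the Tikhonov-damped correction
    theta - A.T (A A.T + I/lambda)^{-1} (A theta - y); the multiplier lambda
    is resolved exactly, once per outer iteration, by a monotone root-find in
    the cached eigenbasis of A A.T so that the post-projection residual
    equals delta (discrepancy principle). An iterate already inside the
    residual ball is left untouched, so measurement noise below the tolerance
    is never chased. With delta = 0 (default) the projection reduces to the
    exact feasibility projection and the solver follows the equality-
    constrained baseline; the initial point is likewise the delta-ball
    Tikhonov solution, which for delta = 0 is the minimum-norm start.

    The resolved multipliers are clipped to [lambda_floor, lambda_cap] and
    recorded in ``lambda_trace_``.
    """

    def __init__(
        self,
        rho: float = 0.8,
        mu: float = 1.0,
        inner_iters: int = 3,
        sigma_min_ratio: float = 1e-4,
        stop_tol: float = 0.005,
        max_outer: int = 200,
        store_history: bool = False,
        lambda_floor: float = 1e-12,
        lambda_cap: float = 1e12,
        error_tolerance: float = 0.0,
        verbose: bool = False,
    ) -> None:
        super().__init__(
            rho, mu, inner_iters, sigma_min_ratio, stop_tol, max_outer, store_history, verbose
        )
        self.lambda_floor = lambda_floor
        self.lambda_cap = lambda_cap
        self.error_tolerance = error_tolerance

    def _validate(self) -> None:
        super()._validate()
        if self.lambda_floor <= 0 or self.lambda_cap < self.lambda_floor:
            raise ValueError("need 0 < lambda_floor <= lambda_cap")
        if self.error_tolerance < 0:
            raise ValueError("error_tolerance must be >= 0")

    def _discrepancy_shift(self, solver, r: np.ndarray, delta: float) -> float:
        """Smallest Tikhonov shift whose damped correction leaves ||residual|| = delta.

        In the eigenbasis the post-projection residual of the correction with
        shift s is sqrt(sum_i (s / (w_i + s))^2 rho_i^2 (+ unsensed part)),
        monotone increasing in s, so the discrepancy equation has a unique
        root; bisection on log s is robust across the ~30 decades the
        tomographic spectra span.
        """
        w = solver.eigvals
        keep = w > solver.PINV_RCOND * solver._scale
        rho_full = solver.eigvecs.T @ r
        unsensed2 = float(np.sum(rho_full[~keep] ** 2))
        rho2 = rho_full[keep] ** 2
        wk = w[keep]

        if unsensed2 >= delta**2:  # tolerance unreachable: project fully
            return 0.0

        def excess(s: float) -> float:
            return float(np.sum((s / (wk + s)) ** 2 * rho2)) + unsensed2 - delta**2

        lo, hi = 1e-12 * wk.min(), 1e12 * wk.max()
        if excess(lo) >= 0:
            return 0.0
        if excess(hi) <= 0:
            return hi
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if excess(mid) > 0:
                hi = mid
            else:
                lo = mid
            if hi / lo < 1 + 1e-12:
                break
        return float(np.sqrt(lo * hi))

    def _initial_theta(self, op, y, solver):
        delta = self.error_tolerance
        if np.linalg.norm(y) <= delta:
            return np.zeros(op.shape[1])
        s = self._discrepancy_shift(solver, np.asarray(y, dtype=float).ravel(), delta)
        if s == 0.0:
            return op.rmatvec(solver.feasibility_solve(y))
        return op.rmatvec(solver.solve(y, s))

    def _outer_setup(self, op, y, solver, theta, sigma):
        # the multiplier is resolved at the first inner gradient step (the
        # point the projection actually acts on) and then held fixed for the
        # whole internal loop of this sigma
        theta_grad = _gradient_step(theta, sigma, self.mu)
        r = op.matvec(theta_grad) - y
        if np.linalg.norm(r) <= self.error_tolerance:
            return self.lambda_cap  # inside the residual ball: no pull needed
        s = self._discrepancy_shift(solver, r, self.error_tolerance)
        lam = self.lambda_cap if s == 0.0 else 1.0 / s
        return float(np.clip(lam, self.lambda_floor, self.lambda_cap))

    def _project(self, op, y, solver, theta, lam):
        r = op.matvec(theta) - y
        if np.linalg.norm(r) <= self.error_tolerance:
            return theta
        return theta - op.rmatvec(solver.solve(r, 1.0 / lam))


# -- functional wrappers --------------------------------------------------


def _estimator_kwargs(cfg: SolverConfig, store_history: bool) -> dict:
    return dict(
        rho=cfg.rho,
        mu=cfg.mu,
        inner_iters=cfg.inner_iters,
        sigma_min_ratio=cfg.sigma_min_ratio,
        stop_tol=cfg.stop_tol,
        max_outer=cfg.max_outer,
        store_history=store_history,
    )


def _result(est: _SmoothedL0Base) -> SolverResult:
    return SolverResult(
        theta_hat=est.coef_,
        image_hat=est.image(),
        sigma_trace=est.sigma_trace_,
        lambda_trace=est.lambda_trace_,
        residual_trace=est.residual_trace_,
        n_outer=est.n_iter_,
        converged=est.converged_,
        history=est.history_,
    )


def sl0_solve(A, y, cfg: SolverConfig | None = None, store_history: bool = False) -> SolverResult:
    """Run the SL0 baseline on (A, y) and package the result."""
    cfg = cfg or SolverConfig()
    est = SL0(**_estimator_kwargs(cfg, store_history))
    return _result(est.fit(A, y))


def resl0_solve(A, y, cfg: SolverConfig | None = None, store_history: bool = False) -> SolverResult:
    """Run the error-tolerant ReSL0 solver on (A, y) and package the result."""
    cfg = cfg or SolverConfig()
    est = ReSL0(
        lambda_floor=cfg.lambda_floor,
        lambda_cap=cfg.lambda_cap,
        error_tolerance=cfg.error_tolerance,
        **_estimator_kwargs(cfg, store_history),
    )
    return _result(est.fit(A, y))
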