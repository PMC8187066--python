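"""Orthonormal wavelet sparsity basis and the composed sensing operator A = K * Psi.

The reconstruction works on wavelet coefficients theta with X = Psi @ theta.
Psi is kept unitary (orthogonal wavelet family, periodization boundary), so
the analysis transform is simultaneously the inverse and the adjoint of the
synthesis transform; the Gram matrix of the composed sensing operator then
equals that of K alone, which the solvers exploit.
"""

from __future__ import annotations

import numpy as np
import pywt

from .forward_model import MeasurementModel
from .phantoms import PhantomImage

__all__ = [
    "WaveletBasis",
    "SparseCoefficients",
    "analyze",
    "synthesize",
    "compose_sensing",
    "SensingOperator",
    "DenseOperator",
    "as_operator",
]


class WaveletBasis:
    """Unitary 2-D discrete wavelet basis for side_px x side_px images.

    Parameters
    ----------
    side_px : int
        Image side; must be divisible by 2**levels.
    family : str
        Any orthogonal PyWavelets family (default 'db4'), or 'identity' for
        Psi = I (useful for solver tests on synthetic sparse vectors).
    levels : int, optional
        Decomposition depth; defaults to the maximum depth compatible with
        both the filter length and the image side.
    boundary : str
        Signal extension mode; 'periodization' (default) is the only mode
        that keeps the transform unitary.
    """

    def __init__(
        self,
        side_px: int,
        family: str = "db4",
        levels: int | None = None,
        boundary: str = "periodization",
    ) -> None:
        if side_px < 2:
            raise ValueError("side_px must be >= 2")
        self.side_px = side_px
        self.family = family
        self.boundary = boundary
        if family == "identity":
            self.levels = 0
            return
        wavelet = pywt.Wavelet(family)
        if not wavelet.orthogonal:
            raise ValueError(f"wavelet family {family!r} is not orthogonal")
        # levels limited by filter length and by the dyadic divisibility of the side
        dyadic = 0
        s = side_px
        while s % 2 == 0:
            dyadic, s = dyadic + 1, s // 2
        max_level = min(pywt.dwt_max_level(side_px, wavelet.dec_len), dyadic)
        self.levels = max_level if levels is None else levels
        if not 0 <= self.levels <= dyadic:
            raise ValueError(f"levels must be in [0, {dyadic}] for side {side_px}")
        self._wavelet = wavelet
        # fixed packing layout for coefficient <-> flat-vector conversion
        coeffs = pywt.wavedec2(
            np.zeros((side_px, side_px)), wavelet, mode=boundary, level=self.levels
        )
        arr, self._slices = pywt.coeffs_to_array(coeffs)
        if arr.shape != (side_px, side_px):
            raise ValueError("coefficient packing does not tile the image exactly")

    @property
    def n_coefficients(self) -> int:
        return self.side_px**2

    def analyze(self, image: np.ndarray) -> np.ndarray:
        """theta = Psi^T X: forward wavelet transform, flattened row-major."""
        image = np.asarray(image, dtype=float)
        if image.shape != (self.side_px, self.side_px):
            raise ValueError(
                f"expected a ({self.side_px}, {self.side_px}) image, got {image.shape}"
            )
        if self.family == "identity":
            return image.ravel().copy()
        coeffs = pywt.wavedec2(image, self._wavelet, mode=self.boundary, level=self.levels)
        arr, _ = pywt.coeffs_to_array(coeffs)
        return arr.ravel()

    def synthesize(self, theta: np.ndarray) -> np.ndarray:
        """X = Psi @ theta: inverse wavelet transform to a square image."""
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.size != self.n_coefficients:
            raise ValueError(f"expected {self.n_coefficients} coefficients, got {theta.size}")
        if self.family == "identity":
            return theta.reshape(self.side_px, self.side_px).copy()
        arr = theta.reshape(self.side_px, self.side_px)
        coeffs = pywt.array_to_coeffs(arr, self._slices, output_format="wavedec2")
        return pywt.waverec2(coeffs, self._wavelet, mode=self.boundary)

    def synthesis_matrix(self) -> np.ndarray:
        """Dense N x N Psi (columns are basis atoms). Small sides only."""
        n = self.n_coefficients
        if n > 4096:
            raise ValueError("dense synthesis matrix is restricted to side_px <= 64")
        Psi = np.empty((n, n))
        e = np.zeros(n)
        for i in range(n):
            e[i] = 1.0
            Psi[:, i] = self.synthesize(e).ravel()
            e[i] = 0.0
        return Psi


class SparseCoefficients:
    """A wavelet coefficient vector theta tied to its basis."""

    def __init__(self, theta: np.ndarray, basis: WaveletBasis) -> None:
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.size != basis.n_coefficients:
            raise ValueError(
                f"theta has length {theta.size}, basis expects {basis.n_coefficients}"
            )
        self.theta = theta
        self.basis = basis


def analyze(image: PhantomImage | np.ndarray, basis: WaveletBasis) -> SparseCoefficients:
    """Transform an image into its sparse coefficient vector."""
    pixels = image.pixels if isinstance(image, PhantomImage) else np.asarray(image)
    return SparseCoefficients(basis.analyze(pixels), basis)


def synthesize(coeffs: SparseCoefficients) -> np.ndarray:
    """Reconstruct the image array from coefficients."""
    return coeffs.basis.synthesize(coeffs.theta)


class SensingOperator:
    """Real-lifted sensing operator A = [Re K; Im K] @ Psi of shape (2M, N).

    Provides matvec/rmatvec actions, the Gram matrix A @ A.T (equal to
    Kr @ Kr.T because Psi is unitary), and a cached eigendecomposition-based
    Gram solver shared by all solvers run on the same operator.
    """

    def __init__(self, model: MeasurementModel, basis: WaveletBasis) -> None:
        if model.grid.side_px != basis.side_px:
            raise ValueError(
                f"model grid side {model.grid.side_px} != basis side {basis.side_px}"
            )
        self.model = model
        self.basis = basis
        self._M = model.n_measurements
        self.shape = (2 * self._M, model.grid.n_pixels)
        self._gram: np.ndarray | None = None
        self._gram_solver = None

    def matvec(self, theta: np.ndarray) -> np.ndarray:
        z = self.model.matvec(self.basis.synthesize(theta).ravel())
        return np.concatenate([z.real, z.imag])

    def rmatvec(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float).ravel()
        if v.size != self.shape[0]:
            raise ValueError(f"expected length {self.shape[0]}, got {v.size}")
        z = v[: self._M] + 1j * v[self._M :]
        g = self.model.rmatvec_conj(z).real  # Kr.T @ v
        return self.basis.analyze(g.reshape(self.model.grid.side_px, -1))

    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = self.model.gram_real()
        return self._gram

    def gram_solver(self):
        # imported here to avoid a circular module dependency
        from .solvers import GramSolver

        if self._gram_solver is None:
            self._gram_solver = GramSolver(self.gram(), n_cols=self.shape[1])
        return self._gram_solver

    def to_dense(self) -> np.ndarray:
        """Explicit (2M, N) matrix Kr @ Psi; small instances only."""
        return self.model.real_matrix() @ self.basis.synthesis_matrix()

    def image_from_coefficients(self, theta: np.ndarray) -> np.ndarray:
        return self.basis.synthesize(theta)


class DenseOperator:
    """Wrapper giving a plain real matrix the sensing-operator interface."""

    def __init__(self, A: np.ndarray) -> None:
        A = np.asarray(A, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        self.A = A
        self.shape = A.shape
        self._gram: np.ndarray | None = None
        self._gram_solver = None

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return self.A @ np.asarray(x, dtype=float).ravel()

    def rmatvec(self, v: np.ndarray) -> np.ndarray:
        return self.A.T @ np.asarray(v, dtype=float).ravel()

    def gram(self) -> np.ndarray:
        if self._gram is None:
            self._gram = self.A @ self.A.T
        return self._gram

    def gram_solver(self):
        from .solvers import GramSolver

        if self._gram_solver is None:
            self._gram_solver = GramSolver(self.gram(), n_cols=self.shape[1])
        return self._gram_solver

    def to_dense(self) -> np.ndarray:
        return self.A


def as_operator(A) -> SensingOperator | DenseOperator:
    """Accept a sensing operator or a plain real matrix."""
    if hasattr(A, "matvec") and hasattr(A, "rmatvec") and hasattr(A, "gram"):
        return A
    return DenseOperator(np.asarray(A))


def compose_sensing(model: MeasurementModel, basis: WaveletBasis) -> SensingOperator:
    """Compose the physics operator with the synthesis basis: A = K * Psi."""
    return SensingOperator(model, basis)
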