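"""Reconstruction quality metrics: PSNR and the normalized 2-norm error (NMAE).

PSNR (dB) is 10 log10(N * MAX_I^2 / ||X - Xhat||_2^2) with MAX_I the maximum
pixel of the ground truth; this equals the conventional
10 log10(MAX_I^2 / MSE). NMAE follows the percent-scale 2-norm ratio
100 * ||Xhat - X||_2 / ||X||_2 — despite the "mean absolute error" name this
is a relative Euclidean error, kept verbatim as defined for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantoms import PhantomImage

__all__ = ["QualityReport", "psnr", "nmae", "quality_report"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, PhantomImage):
        return x.pixels
    return np.asarray(x, dtype=float)


def psnr(x_true, x_hat) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    xt, xh = _as_array(x_true), _as_array(x_hat)
    if xt.shape != xh.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {xh.shape}")
    if np.linalg.norm(xt) == 0:
        raise ValueError("reference image must be nonzero")
    err2 = float(np.sum((xt - xh) ** 2))
    if err2 == 0.0:
        return float("inf")
    max_i = float(xt.max())
    return 10.0 * np.log10(xt.size * max_i**2 / err2)


def nmae(x_true, x_hat) -> float:
    """Percent-scale relative 2-norm error 100 * ||Xhat - X|| / ||X||."""
    xt, xh = _as_array(x_true), _as_array(x_hat)
    if xt.shape != xh.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {xh.shape}")
    ref = np.linalg.norm(xt)
    if ref == 0:
        raise ValueError("reference image must be nonzero")
    return 100.0 * float(np.linalg.norm(xh - xt)) / float(ref)


@dataclass(frozen=True)
class QualityReport:
    psnr_db: float
    nmae: float
    n_pixels: int
    max_intensity: float


def quality_report(x_true, x_hat) -> QualityReport:
    xt = _as_array(x_true)
    return QualityReport(
        psnr_db=psnr(x_true, x_hat),
        nmae=nmae(x_true, x_hat),
        n_pixels=int(xt.size),
        max_intensity=float(xt.max()),
    )
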