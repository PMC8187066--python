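"""Temporal-frequency-domain forward model for circular-scan photoacoustic tomography.

A single transducer scans p positions uniformly spaced on a circle enclosing
the image; at each position the pressure spectrum is sampled at q temporal
frequencies drawn at random from a band. The measurement matrix K maps the
flattened absorbed-energy image X (length N = side^2) to the complex pressure
samples Y (length M = p*q), with entries

    K[(m, n), (i, j)] = i * c * k_n * exp(-i * k_n * |r_m - r_ij|) / |r_m - r_ij|

where k_n = 2*pi*f_n / c is the wavenumber, r_m the detector position and
r_ij the pixel center. Global physical constants (Grueneisen parameter,
1/(4*pi*c) factors) are folded into a single unit scale factor: the same K is
used for simulation and inversion, so any global scale cancels.

Because X is real while K and Y are complex, the inversion path works on the
real-lifted system: Kr = [Re K; Im K] (2M x N real) and y = [Re Y; Im Y].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phantoms import PhantomImage

__all__ = [
    "GeometryError",
    "ImageGrid",
    "ScanGeometry",
    "FrequencySampling",
    "MeasurementModel",
    "PressureData",
    "build_measurement_matrix",
    "simulate_pressure",
    "add_noise",
    "save_measurements",
    "load_measurements",
    "export_pressure_csv",
]

#: Minimum admissible detector-to-pixel distance (1 micrometre, in mm). A
#: violation signals a mis-configured geometry rather than a physical setup.
DISTANCE_FLOOR_MM = 1e-3


class GeometryError(ValueError):
    """Scan geometry incompatible with the image grid."""


@dataclass(frozen=True)
class ImageGrid:
    """Square pixel lattice centred on the origin.

    Pixel centres span [-extent/2 + d/2, extent/2 - d/2] in both axes with
    d = extent_mm / side_px; flattening is row-major (i, j) -> i * side + j.
    """

    side_px: int
    extent_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.side_px < 2:
            raise ValueError("side_px must be >= 2")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")

    @property
    def n_pixels(self) -> int:
        return self.side_px**2

    @property
    def pixel_size_mm(self) -> float:
        return self.extent_mm / self.side_px

    @property
    def pixel_coords_mm(self) -> np.ndarray:
        """(N, 2) array of (x, y) pixel-centre coordinates in mm, row-major."""
        d = self.pixel_size_mm
        x = -self.extent_mm / 2 + (np.arange(self.side_px) + 0.5) * d
        y = self.extent_mm / 2 - (np.arange(self.side_px) + 0.5) * d
        xx, yy = np.meshgrid(x, y)  # row i -> y[i], col j -> x[j]
        return np.column_stack([xx.ravel(), yy.ravel()])

    @classmethod
    def for_phantom(cls, phantom: PhantomImage) -> "ImageGrid":
        return cls(phantom.side_length_px, phantom.extent_mm)


@dataclass(frozen=True)
class ScanGeometry:
    """p detector positions uniformly spaced over [0, 2*pi) on a circle."""

    n_positions: int
    radius_mm: float = 40.0

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")

    @property
    def angles_rad(self) -> np.ndarray:
        return 2 * np.pi * np.arange(self.n_positions) / self.n_positions

    @property
    def positions_mm(self) -> np.ndarray:
        a = self.angles_rad
        return self.radius_mm * np.column_stack([np.cos(a), np.sin(a)])


@dataclass(frozen=True)
class FrequencySampling:
    """q temporal frequencies per detector position, random within a band.

    By default each position receives an independent draw (maximising
    incoherence); set ``share_across_positions`` to reuse one draw everywhere.
    """

    freqs_hz: np.ndarray  # shape (p, q)
    band_mhz: tuple[float, float]
    seed: int
    share_across_positions: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs_hz, dtype=float)
        if f.ndim != 2 or f.shape[1] < 1:
            raise ValueError("freqs_hz must be a (p, q) array with q >= 1")
        lo, hi = self.band_mhz
        if not (0 < lo < hi):
            raise ValueError("band_mhz must satisfy 0 < low < high")
        if f.min() <= lo * 1e6 or f.max() >= hi * 1e6:
            raise ValueError("all frequencies must lie strictly inside the band")
        object.__setattr__(self, "freqs_hz", f)

    @property
    def n_freqs_per_position(self) -> int:
        return self.freqs_hz.shape[1]

    def wavenumbers(self, sound_speed_m_s: float) -> np.ndarray:
        """k_n = 2*pi*f_n / c, in 1/m, shape (p, q)."""
        return 2 * np.pi * self.freqs_hz / sound_speed_m_s

    @classmethod
    def random(
        cls,
        n_positions: int,
        n_freqs: int,
        band_mhz: tuple[float, float] = (0.2, 3.0),
        seed: int = 0,
        share_across_positions: bool = False,
    ) -> "FrequencySampling":
        rng = np.random.default_rng(seed)
        lo, hi = band_mhz
        if share_across_positions:
            row = rng.uniform(lo * 1e6, hi * 1e6, size=n_freqs)
            f = np.tile(row, (n_positions, 1))
        else:
            f = rng.uniform(lo * 1e6, hi * 1e6, size=(n_positions, n_freqs))
        return cls(f, band_mhz, seed, share_across_positions)


class MeasurementModel:
    """The M x N complex measurement operator K for one scan configuration.

    Rows are grouped by detector position then frequency (row m*q + n). In
    dense mode the full complex matrix is stored; in matrix-free mode blocks
    are recomputed on demand with identical semantics.
    """

    def __init__(
        self,
        grid: ImageGrid,
        geometry: ScanGeometry,
        freqs: FrequencySampling,
        sound_speed_m_s: float = 1500.0,
        dense: bool = True,
    ) -> None:
        if sound_speed_m_s <= 0:
            raise ValueError("sound_speed must be positive")
        if geometry.radius_mm <= grid.extent_mm * np.sqrt(2) / 2:
            raise GeometryError(
                f"scan radius {geometry.radius_mm} mm must exceed the grid's "
                f"bounding-circle radius {grid.extent_mm * np.sqrt(2) / 2:.2f} mm"
            )
        self.grid = grid
        self.geometry = geometry
        self.freqs = freqs
        self.sound_speed_m_s = sound_speed_m_s
        self.dense = dense

        # detector-to-pixel distances, in metres, shape (p, N)
        diff = geometry.positions_mm[:, None, :] - grid.pixel_coords_mm[None, :, :]
        dist_mm = np.sqrt((diff**2).sum(axis=2))
        if dist_mm.min() < DISTANCE_FLOOR_MM:
            raise GeometryError(
                f"minimum detector-pixel distance {dist_mm.min():.2e} mm is below "
                f"the {DISTANCE_FLOOR_MM} mm floor"
            )
        self._dist_m = dist_mm * 1e-3
        self._k = freqs.wavenumbers(sound_speed_m_s)  # (p, q), 1/m
        # One global normalization constant (the only free scale of the model,
        # into which all dropped physical constants are folded): entries are
        # divided by c * k_mid / r_scan so that a typical |K| entry is O(1).
        # A global scale cancels between simulation and inversion but keeps
        # the adaptive regularization weight of the solvers on a sane scale.
        f_mid = 0.5 * (freqs.band_mhz[0] + freqs.band_mhz[1]) * 1e6
        self.scale_factor = 2 * np.pi * f_mid / (geometry.radius_mm * 1e-3)
        self._K: np.ndarray | None = self._assemble() if dense else None

    # -- shapes -----------------------------------------------------------
    @property
    def n_measurements(self) -> int:
        return self.geometry.n_positions * self.freqs.n_freqs_per_position

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_measurements, self.grid.n_pixels)

    # -- assembly ---------------------------------------------------------
    def _block(self, m: int) -> np.ndarray:
        """Rows of K for detector position m: shape (q, N)."""
        d = self._dist_m[m]  # (N,)
        k = self._k[m][:, None]  # (q, 1)
        block = (1j * self.sound_speed_m_s * k) * np.exp(-1j * k * d[None, :]) / d[None, :]
        return block / self.scale_factor

    def _assemble(self) -> np.ndarray:
        return np.vstack([self._block(m) for m in range(self.geometry.n_positions)])

    @property
    def K(self) -> np.ndarray:
        """The dense complex matrix (assembled on first access if matrix-free)."""
        if self._K is None:
            return self._assemble()
        return self._K

    def columns(self, idx: np.ndarray) -> np.ndarray:
        """Complex columns K[:, idx] without assembling the full matrix."""
        if self._K is not None:
            return self._K[:, idx]
        d = self._dist_m[:, idx]  # (p, n_idx)
        q = self.freqs.n_freqs_per_position
        out = np.empty((self.n_measurements, len(idx)), dtype=complex)
        for m in range(self.geometry.n_positions):
            k = self._k[m][:, None]
            dm = d[m][None, :]
            out[m * q : (m + 1) * q] = (
                (1j * self.sound_speed_m_s * k) * np.exp(-1j * k * dm) / dm
            ) / self.scale_factor
        return out

    # -- actions ----------------------------------------------------------
    def matvec(self, x: np.ndarray) -> np.ndarray:
        """K @ x for a real or complex length-N vector."""
        x = np.asarray(x).ravel()
        if x.size != self.grid.n_pixels:
            raise ValueError(f"expected length {self.grid.n_pixels}, got {x.size}")
        if self._K is not None:
            return self._K @ x
        q = self.freqs.n_freqs_per_position
        out = np.empty(self.n_measurements, dtype=complex)
        for m in range(self.geometry.n_positions):
            out[m * q : (m + 1) * q] = self._block(m) @ x
        return out

    def rmatvec_conj(self, z: np.ndarray) -> np.ndarray:
        """K^H @ z for a complex length-M vector."""
        z = np.asarray(z).ravel()
        if z.size != self.n_measurements:
            raise ValueError(f"expected length {self.n_measurements}, got {z.size}")
        if self._K is not None:
            # K^H z computed as conj(conj(z) @ K) to avoid materialising K^H
            return np.conj(np.conj(z) @ self._K)
        q = self.freqs.n_freqs_per_position
        out = np.zeros(self.grid.n_pixels, dtype=complex)
        for m in range(self.geometry.n_positions):
            out += self._block(m).conj().T @ z[m * q : (m + 1) * q]
        return out

    def real_matrix(self) -> np.ndarray:
        """The real-lifted (2M, N) matrix [Re K; Im K]."""
        K = self.K
        return np.vstack([K.real, K.imag])

    def gram_real(self, chunk: int = 2048) -> np.ndarray:
        """G = Kr @ Kr.T, the (2M, 2M) real Gram matrix of the lifted system.

        Accumulated over pixel-column chunks so the real-lifted matrix is
        never materialised in full (it would double the memory of K).
        """
        M2 = 2 * self.n_measurements
        G = np.zeros((M2, M2))
        for start in range(0, self.grid.n_pixels, chunk):
            idx = np.arange(start, min(start + chunk, self.grid.n_pixels))
            C = self.columns(idx)
            Cr = np.vstack([C.real, C.imag])
            G += Cr @ Cr.T
        return G

    def config(self) -> dict:
        """Self-describing configuration sufficient to rebuild this model."""
        return {
            "side_px": self.grid.side_px,
            "extent_mm": self.grid.extent_mm,
            "sound_speed": self.sound_speed_m_s,
            "n_positions": self.geometry.n_positions,
            "radius_mm": self.geometry.radius_mm,
            "n_freqs": self.freqs.n_freqs_per_position,
            "band_mhz": list(self.freqs.band_mhz),
            "freq_seed": self.freqs.seed,
            "share_freqs": self.freqs.share_across_positions,
        }

    @classmethod
    def from_config(cls, cfg: dict, dense: bool = True) -> "MeasurementModel":
        grid = ImageGrid(int(cfg["side_px"]), float(cfg["extent_mm"]))
        geom = ScanGeometry(int(cfg["n_positions"]), float(cfg["radius_mm"]))
        freqs = FrequencySampling.random(
            geom.n_positions,
            int(cfg["n_freqs"]),
            tuple(cfg["band_mhz"]),
            int(cfg["freq_seed"]),
            bool(cfg.get("share_freqs", False)),
        )
        return cls(grid, geom, freqs, float(cfg["sound_speed"]), dense=dense)


@dataclass(frozen=True)
class PressureData:
    """Complex pressure samples Y (length M) with noise bookkeeping."""

    Y: np.ndarray
    snr_db: float | None = None  # None means noiseless
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "Y", np.asarray(self.Y, dtype=complex).ravel())

    @property
    def real_vector(self) -> np.ndarray:
        """The lifted real measurement vector [Re Y; Im Y] of length 2M."""
        return np.concatenate([self.Y.real, self.Y.imag])


def build_measurement_matrix(
    grid: ImageGrid,
    geometry: ScanGeometry,
    freqs: FrequencySampling,
    sound_speed: float = 1500.0,
    dense: bool = True,
) -> MeasurementModel:
    """Assemble the measurement operator K for one scan configuration."""
    return MeasurementModel(grid, geometry, freqs, sound_speed, dense=dense)


def simulate_pressure(model: MeasurementModel, phantom: PhantomImage) -> PressureData:
    """Noiseless forward simulation Y = K @ flatten(phantom)."""
    if phantom.side_length_px != model.grid.side_px:
        raise ValueError(
            f"phantom side {phantom.side_length_px} does not match grid side {model.grid.side_px}"
        )
    return PressureData(model.matvec(phantom.flatten()))


def add_noise(data: PressureData, snr_db: float, seed: int = 0) -> PressureData:
    """Add circular white Gaussian noise at an exact signal-to-noise ratio.

    The drawn noise vector is renormalised so that
    10 * log10(||Y||^2 / ||e||^2) equals ``snr_db`` exactly.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    y = data.Y
    y_norm = np.linalg.norm(y)
    if y_norm == 0:
        raise ValueError("SNR is undefined for a zero measurement vector")
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(y.size) + 1j * rng.standard_normal(y.size)
    e *= y_norm * 10 ** (-snr_db / 20) / np.linalg.norm(e)
    return PressureData(y + e, snr_db=snr_db, noise_seed=seed)


# -- disk container -------------------------------------------------------

_REQUIRED_KEYS = (
    "side_px",
    "extent_mm",
    "sound_speed",
    "n_positions",
    "radius_mm",
    "n_freqs",
    "band_mhz",
    "freq_seed",
)


def save_measurements(prefix: str | Path, model: MeasurementModel, data: PressureData) -> Path:
    """Write Y (.npy) plus a JSON sidecar describing the scan configuration.

    Returns the sidecar path; ``load_measurements`` accepts either path.
    """
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), data.Y)
    meta = model.config()
    meta.update({"snr_db": data.snr_db, "noise_seed": data.noise_seed})
    sidecar = prefix.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return sidecar


def load_measurements(path: str | Path, dense: bool = True) -> tuple[MeasurementModel, PressureData]:
    """Rebuild the measurement model and data from a saved container."""
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(sidecar)
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _REQUIRED_KEYS if k not in meta]
    if missing:
        raise ValueError(f"measurement sidecar is missing keys: {missing}")
    model = MeasurementModel.from_config(meta, dense=dense)
    Y = np.load(path.with_suffix(".npy"))
    if Y.size != model.n_measurements:
        raise ValueError(
            f"stored Y has length {Y.size}, geometry implies {model.n_measurements}"
        )
    return model, PressureData(Y, meta.get("snr_db"), meta.get("noise_seed"))


def export_pressure_csv(data: PressureData, path: str | Path) -> None:
    """Human-readable CSV of the pressure samples (index, re, im)."""
    import pandas as pd

    pd.DataFrame(
        {"index": np.arange(data.Y.size), "re": data.Y.real, "im": data.Y.imag}
    ).to_csv(Path(path), index=False)
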