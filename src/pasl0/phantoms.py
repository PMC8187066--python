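"""Synthetic absorbed-energy phantoms for 2-D photoacoustic simulation studies.

Three procedural test objects are provided: the classical Shepp-Logan head
phantom, a seeded vessel-like phantom of sparse curvilinear absorbers, and a
deterministic resolution phantom (bar groups at decreasing pitch plus disks).
All phantoms are square maps of dimensionless absorbed energy density scaled
to [0, 1], the convention used throughout the reconstruction pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "PhantomImage",
    "SHEPP_LOGAN_ELLIPSES",
    "generate_shepp_logan",
    "generate_vessel_phantom",
    "generate_resolution_phantom",
    "generate_phantom",
    "save_png",
    "save_array",
    "load_image",
]


@dataclass(frozen=True)
class PhantomImage:
    """A square ground-truth absorbed-energy map with values in [0, 1].

    Parameters
    ----------
    pixels : ndarray of shape (side, side)
        Dimensionless absorbed energy density.
    extent_mm : float
        Physical side length of the imaged square region, in mm.
    """

    pixels: np.ndarray
    extent_mm: float = 30.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"phantom must be square 2-D, got shape {px.shape}")
        if px.shape[0] < 8:
            raise ValueError(f"phantom side must be >= 8 px, got {px.shape[0]}")
        if not np.all(np.isfinite(px)):
            raise ValueError("phantom contains non-finite values")
        if px.min() < -1e-12 or px.max() > 1.0 + 1e-12:
            raise ValueError("phantom values must lie in [0, 1]")
        if self.extent_mm <= 0:
            raise ValueError("extent_mm must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def side_length_px(self) -> int:
        return self.pixels.shape[0]

    def flatten(self) -> np.ndarray:
        """Row-major flattening (i, j) -> i * side + j, the X vector."""
        return self.pixels.ravel(order="C")


# Classical (non-modified) Shepp-Logan ellipse set:
# (intensity, semi-axis a, semi-axis b, x0, y0, rotation angle in degrees).
# Coordinates live in the unit square [-1, 1]^2 with y pointing up.
SHEPP_LOGAN_ELLIPSES: tuple[tuple[float, float, float, float, float, float], ...] = (
    (2.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.98, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.02, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.02, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.01, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.01, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.01, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.01, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.01, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


def _unit_pixel_centers(side_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates on [-1, 1]^2, y axis pointing up."""
    step = 2.0 / side_px
    x = -1.0 + (np.arange(side_px) + 0.5) * step
    y = 1.0 - (np.arange(side_px) + 0.5) * step
    return np.meshgrid(x, y)  # xx[i, j], yy[i, j]


def _rescale01(img: np.ndarray) -> np.ndarray:
    lo, hi = img.min(), img.max()
    if hi - lo <= 0:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def generate_shepp_logan(side_px: int, extent_mm: float = 30.0) -> PhantomImage:
    """Rasterize the classical 10-ellipse Shepp-Logan head phantom.

    Each pixel takes the summed intensity of all ellipses whose region
    contains the pixel-center coordinate (point sampling, no anti-aliasing);
    the result is min-max rescaled to [0, 1].
    """
    if side_px < 8:
        raise ValueError(f"side_px must be >= 8, got {side_px}")
    xx, yy = _unit_pixel_centers(side_px)
    img = np.zeros((side_px, side_px))
    for inten, a, b, x0, y0, phi_deg in SHEPP_LOGAN_ELLIPSES:
        phi = np.deg2rad(phi_deg)
        xr = (xx - x0) * np.cos(phi) + (yy - y0) * np.sin(phi)
        yr = -(xx - x0) * np.sin(phi) + (yy - y0) * np.cos(phi)
        img += inten * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return PhantomImage(_rescale01(img), extent_mm)


def _paint_disk(img: np.ndarray, ci: float, cj: float, radius: float, value: float) -> None:
    side = img.shape[0]
    i0, i1 = int(max(0, np.floor(ci - radius))), int(min(side, np.ceil(ci + radius) + 1))
    j0, j1 = int(max(0, np.floor(cj - radius))), int(min(side, np.ceil(cj + radius) + 1))
    if i0 >= i1 or j0 >= j1:
        return
    ii, jj = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1), indexing="ij")
    mask = (ii - ci) ** 2 + (jj - cj) ** 2 <= radius**2
    patch = img[i0:i1, j0:j1]
    patch[mask] = np.maximum(patch[mask], value)


def generate_vessel_phantom(
    side_px: int, n_branches: int = 6, seed: int = 0, extent_mm: float = 30.0
) -> PhantomImage:
    """Sparse curvilinear vessel-like absorbers on a zero background.

    Each branch is a smooth random walk (a direction with seeded angular
    drift) painted at a constant width of 1-3 px and a constant intensity in
    [0.6, 1]. Deterministic for a fixed seed; the nonzero support stays a
    small fraction of the image, which is the sparsity premise of the
    compressed-sensing pipeline.
    """
    if side_px < 8:
        raise ValueError(f"side_px must be >= 8, got {side_px}")
    if n_branches < 1:
        raise ValueError(f"n_branches must be >= 1, got {n_branches}")
    rng = np.random.default_rng(seed)
    img = np.zeros((side_px, side_px))
    margin = 0.12 * side_px
    for _ in range(n_branches):
        pos = rng.uniform(margin, side_px - margin, size=2)
        angle = rng.uniform(0.0, 2 * np.pi)
        width = int(rng.integers(1, 4))  # 1..3 px
        value = rng.uniform(0.6, 1.0)
        n_steps = int(0.8 * side_px)
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.12)
            pos = pos + np.array([np.sin(angle), np.cos(angle)])
            if not (1 <= pos[0] < side_px - 1 and 1 <= pos[1] < side_px - 1):
                break
            _paint_disk(img, pos[0], pos[1], width / 2.0, value)
    return PhantomImage(img, extent_mm)


def generate_resolution_phantom(side_px: int, extent_mm: float = 30.0) -> PhantomImage:
    """Deterministic bar/disk resolution target.

    Four groups of four parallel vertical bars at decreasing pitch occupy the
    left half; two disks of different radius and contrast sit on the right.
    Values lie in {0} union [0.5, 1].
    """
    if side_px < 32:
        raise ValueError(f"side_px must be >= 32, got {side_px}")
    s = side_px
    img = np.zeros((s, s))
    # bar groups: (width fraction, top fraction); pitch = 2 * width
    groups = ((0.060, 0.05), (0.045, 0.29), (0.030, 0.53), (0.020, 0.77))
    for w_frac, top_frac in groups:
        w = max(1, round(w_frac * s))
        top = round(top_frac * s)
        height = max(2, round(0.18 * s))
        j = round(0.08 * s)
        for _ in range(4):
            img[top : min(top + height, s), j : min(j + w, s)] = 1.0
            j += 2 * w
    _paint_disk(img, 0.28 * s, 0.72 * s, 0.10 * s, 0.85)
    _paint_disk(img, 0.65 * s, 0.72 * s, 0.055 * s, 0.65)
    return PhantomImage(img, extent_mm)


_GENERATORS = {
    "shepp-logan": generate_shepp_logan,
    "vessel": generate_vessel_phantom,
    "resolution": generate_resolution_phantom,
}


def generate_phantom(name: str, side_px: int, extent_mm: float = 30.0, seed: int = 0) -> PhantomImage:
    """Generate a named phantom ('shepp-logan', 'vessel' or 'resolution')."""
    if name not in _GENERATORS:
        raise ValueError(f"unknown phantom {name!r}; choose from {sorted(_GENERATORS)}")
    if name == "vessel":
        return generate_vessel_phantom(side_px, seed=seed, extent_mm=extent_mm)
    return _GENERATORS[name](side_px, extent_mm=extent_mm)


def save_png(phantom: PhantomImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG (values mapped 0..1 -> 0..255)."""
    arr = np.clip(np.round(phantom.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def save_array(phantom: PhantomImage, path: str | Path) -> None:
    """Write the raw float pixel array (.npy) with a JSON metadata sidecar."""
    path = Path(path)
    np.save(path, phantom.pixels)
    meta = {"extent_mm": phantom.extent_mm, "side_px": phantom.side_length_px}
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_image(path: str | Path, extent_mm: float = 30.0) -> PhantomImage:
    """Read a phantom from .npy or any grayscale-convertible PNG.

    Images are min-max rescaled to [0, 1] so arbitrary user rasters can be
    used as ground truth.
    """
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path).astype(float)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            extent_mm = json.loads(sidecar.read_text()).get("extent_mm", extent_mm)
    else:
        arr = np.asarray(Image.open(path).convert("L"), dtype=float)
    return PhantomImage(_rescale01(arr), extent_mm)
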