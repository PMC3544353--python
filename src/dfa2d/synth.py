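"""Synthetic images for exercising and calibrating the 2D DFA pipeline.

Two families:

* **Shape images** — circles or squares in one of six color modes (white,
  black, red, green, blue, mix) and two size classes, tiled on a regular
  grid over a uniform background.  These mimic benchmark images used to
  probe how shape, color and object size drive the short-range scaling
  exponent.  Within a size class the square's *diagonal* equals the
  circle's diameter, so the two shapes share a characteristic length;
  squares are drawn with their diagonals along the image axes.
* **Calibration surfaces** — isotropic fractional Brownian (fBm) surfaces
  with a chosen Hurst exponent H, synthesized spectrally, and i.i.d.
  uniform noise.  fBm surfaces get smoother as H grows, which a correct
  scaling estimator must recover as a larger alpha1.

Everything is deterministic given the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .core2d import ConfigurationError

__all__ = [
    "COLORS",
    "ShapeSpec",
    "SurfaceSpec",
    "generate_shape_image",
    "generate_surface",
    "simulation_suite",
    "FULL_WIDTH",
    "FULL_HEIGHT",
]

# Full-resolution canvas (width x height in pixels) of the benchmark design.
FULL_WIDTH = 4080
FULL_HEIGHT = 3072

# Full-resolution geometry defaults: characteristic length d (circle
# diameter = square diagonal) and tile pitch per size class.
FULL_D = {"large": 600, "small": 120}
PITCH_FACTOR = 1.5

COLORS = {
    "white": (255, 255, 255),
    "black": (0, 0, 0),
    "red": (255, 0, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
}

SHAPES = ("circle", "square")
COLOR_MODES = ("white", "black", "red", "green", "blue", "mix")
SIZE_CLASSES = ("large", "small")


@dataclass(frozen=True)
class ShapeSpec:
    """Specification of one tiled-shape benchmark image.

    ``d`` is the characteristic length in pixels (circle diameter, equal to
    the square diagonal); ``pitch`` the center-to-center tile spacing.
    White shapes are drawn on a black background, every other color mode on
    white.  ``seed`` only matters for the ``mix`` mode, which cycles red,
    green and blue over tiles in a seed-shuffled order.
    """

    shape: str
    color: str
    size_class: str
    width: int
    height: int
    d: int
    pitch: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ConfigurationError(f"unknown shape {self.shape!r}")
        if self.color not in COLOR_MODES:
            raise ConfigurationError(f"unknown color mode {self.color!r}")
        if self.size_class not in SIZE_CLASSES:
            raise ConfigurationError(f"unknown size class {self.size_class!r}")
        if self.d <= 0 or self.pitch <= 0:
            raise ConfigurationError("d and pitch must be positive")
        if self.d > self.pitch:
            raise ConfigurationError(f"shape (d={self.d}) larger than pitch ({self.pitch})")
        if self.pitch > min(self.width, self.height):
            raise ConfigurationError("pitch larger than canvas")

    @property
    def background(self) -> tuple[int, int, int]:
        return COLORS["black"] if self.color == "white" else COLORS["white"]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SurfaceSpec:
    """Specification of a calibration surface.

    ``kind`` is ``"fbm"`` (isotropic fractional Brownian surface with Hurst
    exponent ``hurst``; radial power spectral density proportional to
    f^(-2(H+1))) or ``"iid_noise"`` (independent uniform pixels).  Output is
    a float grayscale matrix rescaled to 0..255.
    """

    kind: str
    width: int
    height: int
    hurst: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("fbm", "iid_noise"):
            raise ConfigurationError(f"unknown surface kind {self.kind!r}")
        if self.kind == "fbm":
            if self.hurst is None or not (0.0 < self.hurst < 1.0):
                raise ConfigurationError(f"Hurst exponent must be in (0, 1), got {self.hurst}")
        if self.width < 2 or self.height < 2:
            raise ConfigurationError("surface must be at least 2 x 2")

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# Shape rasterization
# --------------------------------------------------------------------------

def _tile_mask(spec: ShapeSpec) -> np.ndarray:
    """Boolean foreground mask of one pitch x pitch tile, shape centered."""
    p, d = spec.pitch, spec.d
    # pixel-center coordinates relative to the tile center
    c = (p - 1) / 2.0
    u = np.arange(p, dtype=np.float64) - c
    if spec.shape == "circle":
        return (u[:, None] ** 2 + u[None, :] ** 2) <= (d / 2.0) ** 2
    # Square drawn with its diagonals along the image axes, so the diagonal
    # (length d, matching the circle diameter) spans the same extent as the
    # circle.  This orientation also keeps the edges off the pixel lattice:
    # an axis-aligned square tiling is exactly separable, and at scales that
    # divide its edge positions every segment of the integrated surface is
    # exactly planar, collapsing F(s) to zero.
    return (np.abs(u[:, None]) + np.abs(u[None, :])) <= d / 2.0


def generate_shape_image(spec: ShapeSpec) -> np.ndarray:
    """Render a ShapeSpec to an RGB uint8 array of shape (height, width, 3).

    Tiles are laid on a regular grid anchored at the top-left corner:
    exactly ``floor(width/pitch) * floor(height/pitch)`` of them, each fully
    inside the canvas and disjoint from its neighbors.
    """
    p = spec.pitch
    nx, ny = spec.width // p, spec.height // p
    img = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    img[:] = spec.background
    mask = _tile_mask(spec)

    if spec.color == "mix":
        rng = np.random.default_rng(spec.seed)
        order = [COLORS[name] for name in rng.permutation(["red", "green", "blue"])]
        for t in range(nx * ny):
            iy, ix = divmod(t, nx)
            tile = img[iy * p:(iy + 1) * p, ix * p:(ix + 1) * p]
            tile[mask] = order[t % 3]
    else:
        fg = COLORS[spec.color]
        block = np.tile(mask, (ny, nx))
        img[: ny * p, : nx * p][block] = fg
    return img


# --------------------------------------------------------------------------
# Calibration surfaces
# --------------------------------------------------------------------------

def generate_surface(spec: SurfaceSpec) -> np.ndarray:
    """Synthesize a calibration surface as a float64 grayscale matrix (0..255)."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.height, spec.width)
    if spec.kind == "iid_noise":
        return rng.uniform(0.0, 255.0, size=shape)

    # fBm: shape the spectrum of complex Gaussian white noise so the power
    # spectral density falls off as f^(-2(H+1)), i.e. amplitude ~ f^-(H+1).
    fy = np.fft.fftfreq(spec.height)[:, None]
    fx = np.fft.fftfreq(spec.width)[None, :]
    f = np.sqrt(fy**2 + fx**2)
    amp = np.zeros(shape)
    nonzero = f > 0
    amp[nonzero] = f[nonzero] ** (-(spec.hurst + 1.0))
    noise = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    surface = np.fft.ifft2(noise * amp).real
    lo, hi = surface.min(), surface.max()
    if hi - lo <= 0:
        raise ConfigurationError("degenerate surface realization")
    return (surface - lo) * (255.0 / (hi - lo))


# --------------------------------------------------------------------------
# Benchmark suite
# --------------------------------------------------------------------------

def simulation_suite(scale_factor: float = 0.25, seed: int = 0) -> list[ShapeSpec]:
    """The full 2 shapes x 6 colors x 2 sizes factorial: 24 ShapeSpecs.

    ``scale_factor`` shrinks the full-resolution canvas (4080 x 3072) and
    the per-size geometry together, so the composition is preserved while
    the suite runs at desk scale (default 1/4: 1020 x 768).
    """
    width = int(round(FULL_WIDTH * scale_factor))
    height = int(round(FULL_HEIGHT * scale_factor))
    if width % 4 or height % 4:
        raise ConfigurationError(
            f"scaled canvas {width} x {height} must have dimensions divisible by 4"
        )
    specs = []
    for shape in SHAPES:
        for color in COLOR_MODES:
            for size_class in SIZE_CLASSES:
                d = int(round(FULL_D[size_class] * scale_factor))
                pitch = int(round(d * PITCH_FACTOR))
                specs.append(ShapeSpec(
                    shape=shape, color=color, size_class=size_class,
                    width=width, height=height, d=d, pitch=pitch, seed=seed,
                ))
    return specs
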