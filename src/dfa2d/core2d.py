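"""Two-dimensional detrended fluctuation analysis (2D DFA) of grayscale images.

The pipeline quantifies fractal-like spatial correlation of an image texture:

1. convert to grayscale (ITU-R BT.601 luma),
2. integrate the mean-centered image along rows and columns into a surface,
3. partition the surface into disjoint ``s``-by-``s`` square segments,
4. remove the least-squares plane trend from each segment,
5. average the residual mean-squared errors into a fluctuation ``F(s)``,
6. estimate scaling exponents as slopes of ``log F(s)`` versus ``log s``.

Exponents follow the usual short/long-range split: ``alpha1`` over scales
4..11, ``alpha2`` over scales from 12 up to ``min(M/4, N/4)``, and a global
``alpha`` over the union.  Larger exponents indicate smoother, more
spatially correlated textures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DFAError",
    "InvalidImageError",
    "ImageFormatError",
    "InvalidSegmentError",
    "ScaleRangeError",
    "DegenerateFluctuationError",
    "InsufficientScalesError",
    "ConfigurationError",
    "SegmentGrid",
    "PlaneTrend",
    "FluctuationCurve",
    "AlphaFit",
    "DFAResult",
    "GRAYSCALE_WEIGHTS",
    "ZERO_TOLERANCE",
    "ALPHA1_RANGE",
    "to_grayscale",
    "integrate_2d",
    "make_segment_grid",
    "fit_plane",
    "fluctuation",
    "fluctuation_curve",
    "fit_alpha",
    "long_range_scales",
    "dfa2d",
]

# --------------------------------------------------------------------------
# Configuration constants
# --------------------------------------------------------------------------

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
GRAYSCALE_WEIGHTS = (0.299, 0.587, 0.114)

#: Fluctuation values below this are treated as exact zeros (degenerate).
ZERO_TOLERANCE = 1e-12

#: Scale range of the short-range exponent alpha1 (inclusive).
ALPHA1_RANGE = (4, 11)

#: First scale of the long-range exponent alpha2.
ALPHA2_MIN_SCALE = 12

#: Default density of the log-spaced long-range scale sweep.
SCALES_PER_OCTAVE = 8


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class DFAError(Exception):
    """Base class for all analysis errors."""


class InvalidImageError(DFAError):
    """Image is degenerate (empty, non-finite, or too small to analyze)."""


class ImageFormatError(DFAError):
    """Unsupported array layout or channel count."""


class InvalidSegmentError(DFAError):
    """Segment handed to the plane fit is not a finite square matrix."""


class ScaleRangeError(DFAError):
    """Requested scale violates 4 <= s <= min(M/4, N/4)."""


class DegenerateFluctuationError(DFAError):
    """F(s) vanished where a log-log fit was requested."""


class InsufficientScalesError(DFAError):
    """Fewer than two usable (s, F) points inside the fit range."""


class ConfigurationError(DFAError):
    """Invalid analysis settings (e.g. empty scale set)."""


# --------------------------------------------------------------------------
# Result containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentGrid:
    """Bookkeeping of the disjoint square partition at one scale.

    The analyzed region is the top-left ``M_s*s`` x ``N_s*s`` block; trailing
    rows/columns that do not fill a segment are discarded.
    """

    s: int
    M_s: int
    N_s: int
    discarded_rows: int
    discarded_cols: int

    @property
    def n_segments(self) -> int:
        return self.M_s * self.N_s


@dataclass(frozen=True)
class PlaneTrend:
    """Least-squares additive plane ``intercept + row_slope*o + col_slope*p``
    over local 1-based coordinates ``o, p`` of a single segment, with the
    mean squared residual of the fit."""

    intercept: float
    row_slope: float
    col_slope: float
    mse: float


@dataclass(frozen=True)
class FluctuationCurve:
    """Fluctuation function sampled at an increasing set of scales."""

    scales: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if scales.ndim != 1 or scales.shape != values.shape:
            raise ConfigurationError("scales and values must be matching 1-D arrays")
        if scales.size and np.any(np.diff(scales) <= 0):
            raise ConfigurationError("scales must be strictly increasing")
        if np.any(values < 0):
            raise ConfigurationError("fluctuation values must be nonnegative")
        object.__setattr__(self, "scales", scales)
        object.__setattr__(self, "values", values)

    @property
    def points(self) -> list[tuple[int, float]]:
        return [(int(s), float(f)) for s, f in zip(self.scales, self.values)]

    def restrict(self, s_min: int, s_max: int) -> "FluctuationCurve":
        mask = (self.scales >= s_min) & (self.scales <= s_max)
        return FluctuationCurve(self.scales[mask], self.values[mask])


@dataclass(frozen=True)
class AlphaFit:
    """Ordinary least-squares fit of ``log F`` on ``log s`` (natural log)."""

    slope: float
    intercept: float
    r_squared: float
    n_scales: int
    s_min: int
    s_max: int


@dataclass(frozen=True)
class DFAResult:
    """Scaling exponents with per-fit diagnostics and provenance.

    ``alpha2``/``alpha`` are ``None`` when the image is too small to provide
    at least two scales above the short-range band.
    """

    alpha: float | None
    alpha1: float
    alpha2: float | None
    fits: dict[str, AlphaFit | None]
    curve: FluctuationCurve
    provenance: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Grayscale conversion
# --------------------------------------------------------------------------

def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a raster image to a 2-D float64 intensity matrix.

    RGB images are reduced with BT.601 luma weights ``0.299 R + 0.587 G +
    0.114 B``; an alpha channel is dropped with a warning; grayscale input
    passes through unchanged (as float64).
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] == 4:
        warnings.warn("dropping alpha channel", stacklevel=2)
        arr = arr[:, :, :3]
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        elif arr.shape[2] == 3:
            if not np.isfinite(arr).all():
                raise InvalidImageError("image contains non-finite pixels")
            w = np.asarray(GRAYSCALE_WEIGHTS)
            return arr @ w
        else:
            raise ImageFormatError(
                f"unsupported channel count: {arr.shape[2]} (expected 1, 3 or 4)"
            )
    if arr.ndim != 2:
        raise ImageFormatError(f"expected 2-D or 3-D raster, got ndim={arr.ndim}")
    if not np.isfinite(arr).all():
        raise InvalidImageError("image contains non-finite pixels")
    return arr


# --------------------------------------------------------------------------
# Integration
# --------------------------------------------------------------------------

def integrate_2d(img: np.ndarray) -> np.ndarray:
    """Integrate a grayscale image into the 2-D analogue of the DFA profile.

    For pixel matrix ``B`` of shape M x N::

        y(m, n) = sum_{i<=m} [B(i, n) - colmean_n] + sum_{j<=n} [B(m, j) - rowmean_m]

    where the means are over the *full* column ``n`` and *full* row ``m``.
    A constant image integrates to the zero surface.
    """
    B = np.asarray(img, dtype=np.float64)
    if B.ndim != 2:
        raise ImageFormatError(f"expected 2-D grayscale matrix, got ndim={B.ndim}")
    if B.shape[0] == 0 or B.shape[1] == 0:
        raise InvalidImageError("image has a zero dimension")
    if not np.isfinite(B).all():
        raise InvalidImageError("image contains non-finite pixels")
    col_term = np.cumsum(B - B.mean(axis=0, keepdims=True), axis=0)
    row_term = np.cumsum(B - B.mean(axis=1, keepdims=True), axis=1)
    return col_term + row_term


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

def make_segment_grid(M: int, N: int, s: int, *, allow_small_scales: bool = False) -> SegmentGrid:
    """Partition an M x N surface into disjoint ``s`` x ``s`` segments.

    The valid range is ``4 <= s <= min(M/4, N/4)``; with
    ``allow_small_scales`` the lower bound relaxes to 2 (used only for
    small-instance cross-checks).  Trailing remainder rows/columns are
    discarded from the bottom/right.
    """
    s = int(s)
    s_lo = 2 if allow_small_scales else 4
    s_hi = min(M, N) / 4.0
    if not (s_lo <= s <= s_hi):
        raise ScaleRangeError(
            f"scale s={s} outside valid range [{s_lo}, {s_hi:g}] "
            f"for an image of {M} x {N} pixels"
        )
    M_s, N_s = M // s, N // s
    return SegmentGrid(
        s=s,
        M_s=M_s,
        N_s=N_s,
        discarded_rows=M - M_s * s,
        discarded_cols=N - N_s * s,
    )


# --------------------------------------------------------------------------
# Plane detrending
# --------------------------------------------------------------------------

def _centered_axis(s: int) -> np.ndarray:
    """1-based axis coordinates 1..s, centered."""
    o = np.arange(1, s + 1, dtype=np.float64)
    return o - o.mean()


def fit_plane(segment: np.ndarray) -> PlaneTrend:
    """Least-squares additive plane fit over one square segment.

    The trend model is ``intercept + row_slope*o + col_slope*p`` with local
    coordinates ``o, p = 1..s`` (no cross term).  Because the constant, the
    centered row coordinate and the centered column coordinate are mutually
    orthogonal over the square grid, the normal equations decouple and the
    coefficients reduce to simple correlation sums.
    """
    y = np.asarray(segment, dtype=np.float64)
    if y.ndim != 2 or y.shape[0] != y.shape[1]:
        raise InvalidSegmentError(f"segment must be square, got shape {y.shape}")
    s = y.shape[0]
    if s < 2:
        raise InvalidSegmentError("segment side must be >= 2")
    if not np.isfinite(y).all():
        raise InvalidSegmentError("segment contains non-finite values")

    oc = _centered_axis(s)
    norm = s * float(oc @ oc)  # squared norm of either slope basis vector
    mean = float(y.mean())
    row_slope = float(oc @ y.sum(axis=1)) / norm
    col_slope = float(y.sum(axis=0) @ oc) / norm
    center = (s + 1) / 2.0
    intercept = mean - row_slope * center - col_slope * center

    o_grid = np.arange(1, s + 1, dtype=np.float64)
    trend = intercept + row_slope * o_grid[:, None] + col_slope * o_grid[None, :]
    mse = float(np.mean((y - trend) ** 2))
    return PlaneTrend(intercept=intercept, row_slope=row_slope, col_slope=col_slope, mse=mse)


def _segment_mse_grid(surface: np.ndarray, grid: SegmentGrid) -> np.ndarray:
    """Mean squared plane-fit residual E_{k,l} for every segment, vectorized.

    Exploits the same orthogonal decomposition as :func:`fit_plane`: the
    residual sum of squares is the total sum of squares minus the energy
    captured by the constant and the two slope directions.
    """
    s, M_s, N_s = grid.s, grid.M_s, grid.N_s
    y = surface[: M_s * s, : N_s * s].reshape(M_s, s, N_s, s).transpose(0, 2, 1, 3)
    oc = _centered_axis(s)
    norm = s * float(oc @ oc)
    total = y.sum(axis=(2, 3))
    sumsq = np.einsum("klop,klop->kl", y, y)
    c_row = y.sum(axis=3) @ oc  # per-segment sum of oc[o] * row-sums
    c_col = y.sum(axis=2) @ oc
    sse = sumsq - total**2 / s**2 - c_row**2 / norm - c_col**2 / norm
    return np.maximum(sse, 0.0) / s**2


# --------------------------------------------------------------------------
# Fluctuation function
# --------------------------------------------------------------------------

def fluctuation(surface: np.ndarray, s: int, *, allow_small_scales: bool = False) -> float:
    """Root-mean-square detrended fluctuation of the integrated surface at scale ``s``.

    ``F(s) = sqrt( mean over segments of E_{k,l} )`` where ``E_{k,l}`` is the
    mean squared residual after removing each segment's plane trend.
    """
    surface = np.asarray(surface, dtype=np.float64)
    grid = make_segment_grid(surface.shape[0], surface.shape[1], s,
                             allow_small_scales=allow_small_scales)
    mse = _segment_mse_grid(surface, grid)
    return float(np.sqrt(mse.mean()))


def fluctuation_curve(img: np.ndarray, scales, *,
                      allow_small_scales: bool = False) -> FluctuationCurve:
    """Evaluate F(s) of a grayscale image over a set of scales.

    The image is integrated once and the surface reused across scales;
    each (s, F) point is independent of which other scales are requested.
    """
    scales = sorted({int(s) for s in np.atleast_1d(np.asarray(scales, dtype=int))})
    if not scales:
        raise ConfigurationError("empty scale set")
    surface = integrate_2d(img)
    values = [fluctuation(surface, s, allow_small_scales=allow_small_scales)
              for s in scales]
    return FluctuationCurve(np.asarray(scales), np.asarray(values))


# --------------------------------------------------------------------------
# Exponent fitting
# --------------------------------------------------------------------------

def fit_alpha(curve: FluctuationCurve, s_min: int, s_max: int) -> AlphaFit:
    """Slope of log F versus log s over the curve points inside [s_min, s_max].

    Ordinary least squares with equal weight per scale; natural logs
    internally (the slope is log-base invariant).  Raises if any in-range
    F is (numerically) zero or fewer than two points are available.
    """
    sub = curve.restrict(s_min, s_max)
    if np.any(sub.values <= ZERO_TOLERANCE):
        raise DegenerateFluctuationError(
            f"F(s) vanishes inside [{s_min}, {s_max}]; log-log fit undefined "
            "(the integrated surface is planar within every segment there)"
        )
    if sub.scales.size < 2:
        raise InsufficientScalesError(
            f"need >= 2 scales with F > 0 inside [{s_min}, {s_max}], "
            f"got {sub.scales.size}"
        )
    x = np.log(sub.scales.astype(np.float64))
    z = np.log(sub.values)
    slope, intercept = np.polyfit(x, z, 1)
    resid = z - (slope * x + intercept)
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return AlphaFit(slope=float(slope), intercept=float(intercept), r_squared=r2,
                    n_scales=int(sub.scales.size),
                    s_min=int(sub.scales.min()), s_max=int(sub.scales.max()))


def long_range_scales(s_max: int, *, s_min: int = ALPHA2_MIN_SCALE,
                      per_octave: int = SCALES_PER_OCTAVE) -> list[int]:
    """Log-spaced integer scales in [s_min, s_max] at ~``per_octave`` per octave.

    Endpoints are always included; duplicates after rounding are dropped.
    A dense integer sweep up to several hundred pixels buys nothing for the
    slope estimate, so the long-range band is sampled logarithmically.
    """
    if s_max < s_min:
        return []
    n_octaves = np.log2(s_max / s_min)
    n = max(2, int(np.ceil(n_octaves * per_octave)) + 1)
    grid = np.geomspace(s_min, s_max, n)
    return sorted({int(round(v)) for v in grid})


def dfa2d(image: np.ndarray, *,
          alpha1_range: tuple[int, int] = ALPHA1_RANGE,
          scales_per_octave: int = SCALES_PER_OCTAVE,
          image_id: str | None = None) -> DFAResult:
    """Full 2D DFA of a raster image: exponents alpha, alpha1, alpha2.

    Runs grayscale conversion, integration and the fluctuation curve over
    the union of the short-range integer scales ``alpha1_range[0]..[1]``
    and a log-spaced long-range sweep up to ``min(M/4, N/4)``, then fits
    the three exponents.  ``alpha2`` and ``alpha`` are omitted (with a
    warning) when fewer than two scales exist above the short-range band.
    """
    gray = to_grayscale(image)
    M, N = gray.shape
    s_lo, s_hi = int(alpha1_range[0]), int(alpha1_range[1])
    if s_lo >= s_hi:
        raise ConfigurationError(f"alpha1 range must be increasing, got {alpha1_range}")
    s_max = min(M, N) // 4
    if s_max < s_hi:
        raise InvalidImageError(
            f"image {M} x {N} too small for the short-range band "
            f"(min(M/4, N/4) = {s_max} < {s_hi})"
        )
    if np.ptp(gray) <= ZERO_TOLERANCE:
        raise DegenerateFluctuationError(
            "constant image: the integrated surface is identically zero, "
            "so F(s) = 0 at every scale"
        )

    short_scales = list(range(s_lo, s_hi + 1))
    long_scales = long_range_scales(s_max, s_min=s_hi + 1,
                                    per_octave=scales_per_octave)
    curve = fluctuation_curve(gray, short_scales + long_scales)

    fit1 = fit_alpha(curve, s_lo, s_hi)
    fit2 = fit_global = None
    if len(long_scales) >= 2:
        fit2 = fit_alpha(curve, s_hi + 1, s_max)
        fit_global = fit_alpha(curve, s_lo, s_max)
    else:
        warnings.warn(
            f"fewer than 2 scales above s={s_hi}; alpha2 and global alpha omitted",
            stacklevel=2,
        )

    provenance = {
        "image_id": image_id,
        "shape": [int(M), int(N)],
        "grayscale": "BT.601 luma (0.299, 0.587, 0.114)",
        "scales": [int(s) for s in curve.scales],
        "alpha1_scales": short_scales,
        "alpha2_scales": long_scales,
    }
    return DFAResult(
        alpha=None if fit_global is None else fit_global.slope,
        alpha1=fit1.slope,
        alpha2=None if fit2 is None else fit2.slope,
        fits={"alpha": fit_global, "alpha1": fit1, "alpha2": fit2},
        curve=curve,
        provenance=provenance,
    )
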