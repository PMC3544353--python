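"""Monodimensional detrended fluctuation analysis (the Peng et al. scheme).

Serves both as a standalone analysis of numeric series and as the
conceptual reference for the 2D machinery: a 2D image that is constant
along one axis reduces exactly to the 1D analysis of its profile.

Conventions: windows are disjoint, taken from the start of the series,
with the trailing remainder discarded; detrending is first-order (a
least-squares line per window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core2d import (
    AlphaFit,
    DegenerateFluctuationError,
    FluctuationCurve,
    InvalidImageError,
    ScaleRangeError,
    ZERO_TOLERANCE,
    _centered_axis,
    fit_alpha,
)

__all__ = ["DFA1DResult", "integrate_1d", "fluctuation_1d", "dfa1d"]


@dataclass(frozen=True)
class DFA1DResult:
    alpha: float
    fit: AlphaFit
    curve: FluctuationCurve


def integrate_1d(series: np.ndarray) -> np.ndarray:
    """Profile y(k) = cumulative sum of the mean-centered samples.

    The final profile value is zero up to rounding (the centered sum
    telescopes).
    """
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size == 0:
        raise InvalidImageError("empty series")
    if not np.isfinite(x).all():
        raise InvalidImageError("series contains non-finite samples")
    return np.cumsum(x - x.mean())


def fluctuation_1d(profile: np.ndarray, n: int) -> float:
    """RMS fluctuation of an integrated series at window scale ``n``.

    Each complete disjoint window of length ``n`` is detrended by its
    least-squares line; the residuals are pooled over all included samples.
    """
    y = np.asarray(profile, dtype=np.float64).ravel()
    n = int(n)
    if n < 2 or n > y.size:
        raise ScaleRangeError(f"window scale n={n} invalid for series of length {y.size}")
    W = y.size // n
    yw = y[: W * n].reshape(W, n)
    kc = _centered_axis(n)
    norm = float(kc @ kc)
    total = yw.sum(axis=1)
    slope_num = yw @ kc
    sse = np.einsum("wk,wk->w", yw, yw) - total**2 / n - slope_num**2 / norm
    sse = np.maximum(sse, 0.0)
    return float(np.sqrt(sse.sum() / (W * n)))


def dfa1d(series: np.ndarray, scales) -> DFA1DResult:
    """1D DFA: fluctuation curve over ``scales`` plus the log-log exponent."""
    x = np.asarray(series, dtype=np.float64).ravel()
    if x.size == 0:
        raise InvalidImageError("empty series")
    if np.ptp(x) <= ZERO_TOLERANCE:
        raise DegenerateFluctuationError("constant series: F(n) = 0 at every scale")
    profile = integrate_1d(x)
    scale_list = sorted({int(n) for n in np.atleast_1d(np.asarray(scales, dtype=int))})
    values = [fluctuation_1d(profile, n) for n in scale_list]
    curve = FluctuationCurve(np.asarray(scale_list), np.asarray(values))
    fit = fit_alpha(curve, scale_list[0], scale_list[-1])
    return DFA1DResult(alpha=fit.slope, fit=fit, curve=curve)
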