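"""Shared fixtures and independent brute-force oracles.

The oracles re-derive every stage of the analysis (integration, plane
detrend, fluctuation) with naive loops and generic least squares, entirely
apart from the vectorized implementation they cross-check.
"""

import numpy as np
import pytest


def naive_integrate_2d(B):
    """Direct per-pixel evaluation of the double mean-centered cumulative sum."""
    B = np.asarray(B, dtype=float)
    M, N = B.shape
    y = np.zeros((M, N))
    for m in range(M):
        for n in range(N):
            col = sum(B[i, n] - B[:, n].mean() for i in range(m + 1))
            row = sum(B[m, j] - B[m, :].mean() for j in range(n + 1))
            y[m, n] = col + row
    return y


def naive_plane_fit(segment):
    """Generic least squares of z ~ 1 + o + p via lstsq; returns (coef, mse)."""
    seg = np.asarray(segment, dtype=float)
    s = seg.shape[0]
    o = np.arange(1, s + 1, dtype=float)
    A = np.column_stack([np.ones(s * s), np.repeat(o, s), np.tile(o, s)])
    coef, *_ = np.linalg.lstsq(A, seg.ravel(), rcond=None)
    mse = float(np.mean((seg.ravel() - A @ coef) ** 2))
    return coef, mse


def naive_fluctuation(B, s):
    """Loop-based F(s): integrate, segment, plane-detrend, pool MSEs."""
    y = naive_integrate_2d(B)
    M, N = y.shape
    Ms, Ns = M // s, N // s
    mses = []
    for k in range(Ms):
        for l in range(Ns):
            seg = y[k * s:(k + 1) * s, l * s:(l + 1) * s]
            mses.append(naive_plane_fit(seg)[1])
    return float(np.sqrt(np.mean(mses)))


def naive_fluctuation_1d(x, n):
    """Loop-based 1D F(n): disjoint windows, per-window line detrend."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    W = y.size // n
    k = np.arange(1, n + 1, dtype=float)
    A = np.column_stack([np.ones(n), k])
    sse = 0.0
    for w in range(W):
        seg = y[w * n:(w + 1) * n]
        coef, *_ = np.linalg.lstsq(A, seg, rcond=None)
        sse += float(np.sum((seg - A @ coef) ** 2))
    return np.sqrt(sse / (W * n))


def ols_slope(x, z):
    """Closed-form textbook least-squares slope/intercept."""
    x, z = np.asarray(x, float), np.asarray(z, float)
    sx, sz = x - x.mean(), z - z.mean()
    slope = float((sx @ sz) / (sx @ sx))
    return slope, float(z.mean() - slope * x.mean())


def anova_f_oracle(groups):
    """From-scratch one-way ANOVA F from the sum-of-squares decomposition."""
    arrays = [np.asarray(g, float) for g in groups]
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    dfb, dfw = len(arrays) - 1, allv.size - len(arrays)
    return (ssb / dfb) / (ssw / dfw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
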