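# Methods

## The model

Detrended fluctuation analysis characterizes a signal by how the
root-mean-square residual of its integrated profile, after local trend
removal, grows with the observation scale. A power law F(s) ∝ s^α with
exponent α quantifies long-range correlation: α ≈ 0.5 for uncorrelated
increments, larger α for smoother, persistent structure.

The 2D form used here transfers this to images. The intensity matrix is
integrated cumulatively along rows and columns, each term centered on the
*full* row/column mean (not per-segment means — an intentional reading
that keeps the integration a single global pass and makes constant images
integrate to the exact zero surface). The integrated surface is cut into
disjoint s×s segments, ⌊M/s⌋ per column dimension and ⌊N/s⌋ per row
dimension, with trailing remainder pixels discarded from the bottom/right
only; at the largest admitted scale, min(M/4, N/4), at least 4×4 segments
remain. Each segment is detrended by the least-squares additive plane
a + b·o + c·p over local 1-based coordinates o, p ∈ 1…s. The three basis
directions (constant, centered row coordinate, centered column coordinate)
are mutually orthogonal over a square grid, so the normal equations
decouple and the vectorized residual computation is exact, not iterative.
No o·p cross term is fitted: the plane is the 2D analogue of first-order
(linear) detrending in classical DFA.

The fluctuation function is the RMS of the pooled per-segment mean squared
residuals. Exponents are ordinary least-squares slopes of log F versus
log s with one equally weighted point per scale (natural logs internally;
slopes are base-invariant):

* **α1** — all eight integer scales s = 4…11 (the short-range band),
* **α2** — s = 12 up to min(M/4, N/4),
* **α** — the union of both bands.

Because integration is linear and mean-centered, an affine intensity map
B → aB + c multiplies F(s) by |a| at every scale and leaves all three
exponents unchanged; this holds to ~1e−15 numerically and makes the
exponents insensitive to global illumination and contrast — the practical
reason a color image's channel weighting (BT.601 luma, recorded in each
result's provenance) barely matters for uniformly colored structures.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| α1 band | s = 4…11 (integers) | short-range exponent; needs min(M/4, N/4) ≥ 11 |
| α2 band | s = 12…min(M/4, N/4) | long-range exponent; omitted (with a warning) when fewer than two scales exist above 11 |
| scale sampling | ~8 per octave, log-spaced, deduplicated | above s = 11 a dense integer sweep adds cost but no slope precision |
| scale lower bound | 4 (2 behind `allow_small_scales`, for small-instance cross-checks only) | below s = 4 a 3-parameter plane fit on s² points is too unconstrained |
| zero threshold | F < 1e−12 treated as exact zero | triggers the degenerate-fluctuation error instead of log(0) |
| grayscale | BT.601 luma 0.299 R + 0.587 G + 0.114 B | recorded in provenance so alternates can be compared |

1D DFA mirrors these conventions: disjoint windows anchored at the series
start, remainder discarded, first-order detrending, same log–log fit.

## Synthetic data

**Shape images** emulate a factorial benchmark: {circle, square} ×
{white, black, red, green, blue, mix} × {large, small} = 24 images at a
4080×3072 full-resolution canvas, analyzed by default at 1/4 scale
(1020×768). Geometry defaults: characteristic length d = 600 px (large) /
120 px (small) at full resolution, tile pitch 1.5·d, shapes tiled on a
regular grid anchored at the top-left corner. White shapes are drawn on a
black background, all other modes on white; "mix" cycles red/green/blue
over tiles in a seed-shuffled order. The square is drawn with its
diagonals along the image axes so that the diagonal — the extent matched
to the circle's diameter — spans the same axis range as the circle.
This orientation is also a numerical necessity: an axis-aligned square
tiling is exactly separable (B = bg + k·u(i)v(j)), and when its edge
positions land on multiples of the scale s every segment of the
integrated surface is *exactly* planar, collapsing F(s) to zero and
leaving the log–log fit undefined.

These images are binary-contrast, noise-free, perfectly periodic rasters.
They exercise the geometry-sensitivity of α1 (edge density, object size)
but do not emulate stain variation, illumination gradients, focus blur or
the irregular cell packing of real section images, so passing the suite's
ordering checks says nothing about clinical discriminability — only that
the estimator responds to composition the way it should.

A known limitation surfaced by this suite: at 1/4 resolution the α1 band
s = 4…11 sits at 4× larger s/d than at full resolution. For circles this
band lands in an oscillatory (pitch/scale moiré) part of the fluctuation
curve and the large-vs-small ordering of α1 reverses, while at full
resolution (d = 600 vs 120) the expected ordering holds. The orderings
are therefore scale-regime properties, not invariants of the estimator;
the acceptance test records this honestly (the circle size pairs fail at
desk scale).

**Calibration surfaces**: isotropic fractional Brownian surfaces are
synthesized spectrally — complex Gaussian white noise shaped by an
amplitude ∝ f^−(H+1) (power spectral density ∝ f^−2(H+1)), zero DC, real
part of the inverse FFT, min–max rescaled to 0…255. Mean α1 rises
strictly with H over {0.2, 0.5, 0.8} (20 seeds each at 256×256), the core
calibration of the 2D estimator. The periodic FFT synthesis makes the
surfaces wrap-around stationary, which real textures are not; the min–max
rescaling is affine and thus invisible to the exponents. I.i.d. uniform
noise provides the uncorrelated reference. 1D calibration: white Gaussian
noise (N = 4096, scales 4…64, 50 seeds) yields a mean exponent of ≈ 0.53,
within the expected 0.5 ± 0.08 (the small-scale bias of first-order DFA
pushes the slope slightly above 0.5).

## Statistics

Group comparisons use sample mean ± SD (n−1 denominator), one-way ANOVA
(an infinite F with p = 0 is reported, with a warning, in the degenerate
zero-within-variance case), and Tukey HSD pairwise comparisons in the
Tukey–Kramer form, which handles unbalanced designs such as 18/10/10.
Exact adjusted p-values are reported alongside significance flags at the
configured level (default 0.05). The ANOVA/Tukey computations are
delegated to scipy/statsmodels; the test suite cross-checks F against an
independent sum-of-squares decomposition.

## Numerical choices

* All analysis in float64; the vectorized fluctuation agrees with a naive
  loop implementation to ~2e−16 relative (asserted at 1e−10).
* Residual sums of squares are clipped at zero before the square root to
  absorb −1e−18-scale cancellation error.
* Scale sets are deduplicated and sorted; each (s, F) point is computed
  independently, so results do not depend on which other scales were
  requested. Identical input and settings give bit-identical results.
* Degenerate inputs fail loudly with typed errors (constant images,
  out-of-range scales, too-small images, empty scale sets) rather than
  returning NaN.

## Problem sizes

Default analyses and tests run at desk scale: benchmark suite at 1020×768,
calibration surfaces at 256×256, oracle cross-checks at ≤ 32×32. A full
4080×3072 image analyzes in a few seconds; the orderings reported at full
resolution in the limitation note above were measured directly at that
size.
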