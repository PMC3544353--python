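# dfa2d — two-dimensional detrended fluctuation analysis for images

`dfa2d` quantifies the fractal, scale-invariant texture of grayscale or
color raster images with a two-dimensional extension of detrended
fluctuation analysis (DFA). It was built for biological image analysis —
the motivating use case is discriminating histopathology section textures
(e.g. aggressive B-cell lymphoma subtypes) by their short-range scaling
exponent — but it applies to any image whose roughness across spatial
scales carries information.

## Method

For an M×N intensity matrix *B(i, j)* (color input is first reduced with
BT.601 luma weights 0.299/0.587/0.114), the image is integrated along both
axes against its full-column and full-row means:

    y(m, n) = Σ_{i=1..m} [B(i, n) − B̄ⁿ_col] + Σ_{j=1..n} [B(m, j) − B̄ᵐ_row]

The integrated surface is partitioned into ⌊M/s⌋ × ⌊N/s⌋ disjoint s×s
segments (trailing remainders discarded), each segment is detrended by its
least-squares plane *a + b·o + c·p*, and the residual mean squared errors
E_{k,l} are pooled:

    F(s) = sqrt( (1 / M_s N_s) Σ_{k,l} E_{k,l} ),   4 ≤ s ≤ min(M/4, N/4)

A power law F(s) ∝ s^α appears as a line on the log–log plot; its slope is
the scaling exponent. Three fits are reported: the short-range exponent
**α1** over the eight integer scales s = 4…11, the long-range exponent
**α2** over a log-spaced sweep of s = 12…min(M/4, N/4), and the global
**α** over the union. Larger exponents mean smoother, more spatially
correlated texture.

The package also ships the classical monodimensional DFA (`dfa2d.dfa1d`),
synthetic benchmark generators (tiled circle/square images in six color
modes and two sizes; fractional Brownian calibration surfaces), and a
group-comparison layer (mean ± SD, one-way ANOVA, Tukey–Kramer pairwise
tests) for batch studies.

## Worked example

```python
import dfa2d
from dfa2d import synth, stats

# a smooth fractional Brownian surface (Hurst H = 0.7, 256 x 256)
surf = synth.generate_surface(
    synth.SurfaceSpec(kind="fbm", width=256, height=256, hurst=0.7, seed=42))
res = dfa2d.dfa2d(surf)
print(f"alpha1 = {res.alpha1:.3f}")
print(f"alpha2 = {res.alpha2:.3f}")
print(f"alpha  = {res.alpha:.3f}")
```

prints

```
alpha1 = 1.308
alpha2 = 0.999
alpha  = 1.114
```

α1 ≈ 1.3 reflects the strong short-range smoothness of an H = 0.7 surface;
the exponent drops toward ~0.86 for a rough H = 0.2 surface, so α1 orders
textures by roughness. Comparing groups of images works the same way as
comparing patient groups:

```python
groups = {f"H={H}": [dfa2d.dfa2d(synth.generate_surface(synth.SurfaceSpec(
              kind="fbm", width=128, height=128, hurst=H, seed=s))).alpha1
          for s in range(6)] for H in (0.3, 0.5, 0.7)}
print(stats.format_report(stats.anova_tukey(groups)))
```

```
group          n  alpha1 (mean +/- SD)
H=0.3          6  0.951 +/- 0.031
H=0.5          6  1.127 +/- 0.040
H=0.7          6  1.310 +/- 0.049
ANOVA: F(2, 15) = 116.858, P = <0.001
  H=0.3 vs H=0.5: diff = +0.176, P_adj = 5.42e-06 *
  H=0.3 vs H=0.7: diff = +0.359, P_adj = 4.28e-10 *
  H=0.5 vs H=0.7: diff = +0.183, P_adj = 3.38e-06 *
(* significant at P < 0.05, Tukey-adjusted)
```

## Command line

```sh
dfa2d analyze image.png -o result.json        # exponents + F(s) table as JSON
dfa2d batch manifest.csv -o batch.csv --report stats.json
                                              # manifest columns: image,group
dfa2d compare batch.csv -o report.json        # ANOVA + Tukey on alpha1 by group
dfa2d simulate --suite -o images/             # 24-image benchmark suite (PNG)
dfa2d dfa1d series.txt --scales 4:64          # monodimensional DFA
```

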