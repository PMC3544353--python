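"""Unit and property tests for the 2D DFA pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dfa2d
from dfa2d.core2d import (
    ConfigurationError,
    DegenerateFluctuationError,
    ImageFormatError,
    InsufficientScalesError,
    InvalidImageError,
    InvalidSegmentError,
    FluctuationCurve,
    ScaleRangeError,
    ZERO_TOLERANCE,
)
from conftest import naive_fluctuation, naive_plane_fit, ols_slope


# ---------------------------------------------------------------- grayscale

class TestToGrayscale:
    def test_luma_weights_on_pure_channels(self):
        red = np.zeros((1, 1, 3)); red[..., 0] = 255
        blue = np.zeros((1, 1, 3)); blue[..., 2] = 255
        assert dfa2d.to_grayscale(red)[0, 0] == pytest.approx(76.245)
        assert dfa2d.to_grayscale(blue)[0, 0] == pytest.approx(29.07)

    def test_equal_channels_pass_through(self, rng):
        g = rng.uniform(0, 255, (5, 7))
        rgb = np.stack([g, g, g], axis=-1)
        np.testing.assert_allclose(dfa2d.to_grayscale(rgb), g, atol=1e-12)

    def test_grayscale_input_unchanged(self, rng):
        g = rng.uniform(0, 255, (4, 4))
        np.testing.assert_array_equal(dfa2d.to_grayscale(g), g)

    def test_alpha_channel_dropped_with_warning(self):
        rgba = np.zeros((2, 2, 4)); rgba[..., 0] = 255; rgba[..., 3] = 128
        with pytest.warns(UserWarning, match="alpha"):
            out = dfa2d.to_grayscale(rgba)
        assert out[0, 0] == pytest.approx(76.245)

    def test_errors(self):
        with pytest.raises(ImageFormatError):
            dfa2d.to_grayscale(np.zeros((2, 2, 5)))
        with pytest.raises(InvalidImageError):
            dfa2d.to_grayscale(np.array([[np.nan, 1.0], [0.0, 2.0]]))


# --------------------------------------------------------------- integration

class TestIntegrate2D:
    def test_hand_derived_2x2(self):
        surface = dfa2d.integrate_2d([[1, 3], [5, 7]])
        np.testing.assert_allclose(surface, [[-3, -2], [-1, 0]], atol=1e-12)

    def test_constant_image_integrates_to_zero(self):
        np.testing.assert_allclose(dfa2d.integrate_2d(np.full((6, 9), 42.0)), 0.0,
                                   atol=1e-12)

    def test_affine_linearity(self, rng):
        B = rng.uniform(0, 255, (12, 10))
        base = dfa2d.integrate_2d(B)
        np.testing.assert_allclose(dfa2d.integrate_2d(3.5 * B - 40.0), 3.5 * base,
                                   rtol=1e-12, atol=1e-9)

    def test_degenerate_dimensions(self):
        with pytest.raises(InvalidImageError):
            dfa2d.integrate_2d(np.empty((0, 5)))


# -------------------------------------------------------------- segmentation

class TestSegmentGrid:
    @pytest.mark.parametrize(
        "M, N, s, Ms, Ns, drop_r, drop_c",
        [
            (100, 80, 8, 12, 10, 4, 0),
            (16, 16, 4, 4, 4, 0, 0),
            (4080, 3072, 11, 370, 279, 10, 3),
        ],
    )
    def test_floor_bookkeeping(self, M, N, s, Ms, Ns, drop_r, drop_c):
        grid = dfa2d.make_segment_grid(M, N, s)
        assert (grid.M_s, grid.N_s) == (Ms, Ns)
        assert (grid.discarded_rows, grid.discarded_cols) == (drop_r, drop_c)
        assert grid.M_s * s + grid.discarded_rows == M

    def test_scale_bounds_enforced(self):
        with pytest.raises(ScaleRangeError, match=r"\[4, 4\]"):
            dfa2d.make_segment_grid(16, 16, 5)
        with pytest.raises(ScaleRangeError):
            dfa2d.make_segment_grid(100, 100, 3)

    def test_small_scale_testing_mode(self):
        grid = dfa2d.make_segment_grid(8, 8, 2, allow_small_scales=True)
        assert grid.M_s == 4
        with pytest.raises(ScaleRangeError):
            dfa2d.make_segment_grid(8, 8, 2)


# ------------------------------------------------------------ plane detrend

class TestFitPlane:
    def test_exact_plane_recovered(self):
        o = np.arange(1, 8, dtype=float)
        seg = 2.0 + 3.0 * o[:, None] + 4.0 * o[None, :]
        trend = dfa2d.fit_plane(seg)
        assert trend.intercept == pytest.approx(2.0)
        assert trend.row_slope == pytest.approx(3.0)
        assert trend.col_slope == pytest.approx(4.0)
        assert trend.mse == pytest.approx(0.0, abs=1e-18)

    def test_constant_segment(self):
        trend = dfa2d.fit_plane(np.full((5, 5), 7.25))
        assert (trend.row_slope, trend.col_slope) == (0.0, 0.0)
        assert trend.intercept == pytest.approx(7.25)
        assert trend.mse == pytest.approx(0.0, abs=1e-18)

    def test_saddle_residual(self):
        trend = dfa2d.fit_plane(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert trend.row_slope == pytest.approx(0.0)
        assert trend.col_slope == pytest.approx(0.0)
        assert trend.mse == pytest.approx(0.25)

    def test_matches_normal_equations_oracle(self, rng):
        for s in (3, 5, 8):
            seg = rng.normal(size=(s, s))
            coef, mse = naive_plane_fit(seg)
            trend = dfa2d.fit_plane(seg)
            np.testing.assert_allclose(
                [trend.intercept, trend.row_slope, trend.col_slope], coef, atol=1e-10)
            assert trend.mse == pytest.approx(mse, rel=1e-10, abs=1e-12)

    def test_errors(self):
        with pytest.raises(InvalidSegmentError):
            dfa2d.fit_plane(np.zeros((3, 4)))
        with pytest.raises(InvalidSegmentError):
            dfa2d.fit_plane(np.array([[1.0, np.inf], [0.0, 1.0]]))


# ---------------------------------------------------------- fluctuation F(s)

class TestFluctuation:
    def test_constant_image_fluctuates_zero(self):
        surface = dfa2d.integrate_2d(np.full((24, 24), 9.0))
        assert dfa2d.fluctuation(surface, 4) == 0.0

    def test_globally_planar_surface_gives_zero(self):
        o = np.arange(1, 33, dtype=float)
        surface = 1.0 + 0.5 * o[:, None] - 0.25 * o[None, :]
        for s in (4, 8):
            assert dfa2d.fluctuation(surface, s) == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        B = rng.integers(0, 256, (24, 24)).astype(float)
        surface = dfa2d.integrate_2d(B)
        for s in (4, 5, 6):
            fast = dfa2d.fluctuation(surface, s)
            slow = naive_fluctuation(B, s)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_curve_points_independent_of_scale_set(self, rng):
        B = rng.uniform(0, 255, (40, 40))
        lone = dfa2d.fluctuation_curve(B, [4])
        pair = dfa2d.fluctuation_curve(B, [4, 8])
        assert lone.values[0] == pair.values[0]

    def test_curve_on_constant_image_is_zero_everywhere(self):
        curve = dfa2d.fluctuation_curve(np.full((48, 48), 3.0), range(4, 12))
        assert np.all(curve.values == 0.0)
        assert list(curve.scales) == list(range(4, 12))

    def test_empty_scale_set_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            dfa2d.fluctuation_curve(rng.uniform(0, 1, (32, 32)), [])


# ------------------------------------------------------------- alpha fitting

class TestFitAlpha:
    def test_exact_power_law(self):
        s = np.arange(4, 12)
        fit = dfa2d.fit_alpha(FluctuationCurve(s, s.astype(float) ** 0.7), 4, 11)
        assert fit.slope == pytest.approx(0.7)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_scales == 8

    def test_prefactor_goes_to_intercept(self):
        s = np.arange(4, 12)
        fit = dfa2d.fit_alpha(FluctuationCurve(s, 3.0 * s.astype(float)), 4, 11)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(np.log(3.0))

    def test_matches_closed_form_on_noisy_points(self, rng):
        s = np.arange(4, 20)
        F = s**0.6 * np.exp(rng.normal(0, 0.05, s.size))
        fit = dfa2d.fit_alpha(FluctuationCurve(s, F), 4, 19)
        slope, intercept = ols_slope(np.log(s), np.log(F))
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)

    def test_zero_fluctuation_is_degenerate(self):
        curve = FluctuationCurve(np.arange(4, 12), np.zeros(8))
        with pytest.raises(DegenerateFluctuationError):
            dfa2d.fit_alpha(curve, 4, 11)

    def test_single_point_insufficient(self):
        curve = FluctuationCurve(np.array([4, 20]), np.array([1.0, 2.0]))
        with pytest.raises(InsufficientScalesError):
            dfa2d.fit_alpha(curve, 4, 11)


# ------------------------------------------------------------------- dfa2d

class TestDfa2d:
    def test_alpha1_uses_exactly_the_short_band(self, rng):
        res = dfa2d.dfa2d(rng.uniform(0, 255, (96, 64)))
        assert res.provenance["alpha1_scales"] == list(range(4, 12))
        assert res.fits["alpha1"].n_scales == 8
        assert (res.fits["alpha1"].s_min, res.fits["alpha1"].s_max) == (4, 11)

    def test_affine_grayscale_invariance(self, rng):
        B = rng.uniform(0, 255, (96, 80))
        a, b = dfa2d.dfa2d(B), dfa2d.dfa2d(-1.75 * B + 300.0)
        assert b.alpha1 == pytest.approx(a.alpha1, abs=1e-9)
        assert b.alpha2 == pytest.approx(a.alpha2, abs=1e-9)
        assert b.alpha == pytest.approx(a.alpha, abs=1e-9)

    def test_deterministic(self, rng):
        B = rng.uniform(0, 255, (64, 64))
        r1, r2 = dfa2d.dfa2d(B), dfa2d.dfa2d(B)
        assert r1.alpha1 == r2.alpha1
        np.testing.assert_array_equal(r1.curve.values, r2.curve.values)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateFluctuationError, match="constant"):
            dfa2d.dfa2d(np.full((64, 64), 5.0))

    def test_too_small_image_rejected(self, rng):
        with pytest.raises(InvalidImageError, match="too small"):
            dfa2d.dfa2d(rng.uniform(0, 1, (32, 32)))

    def test_alpha2_omitted_below_two_long_scales(self, rng):
        # min(M/4, N/4) = 12 leaves a single scale above 11
        with pytest.warns(UserWarning, match="alpha2"):
            res = dfa2d.dfa2d(rng.uniform(0, 255, (48, 48)))
        assert res.alpha2 is None and res.alpha is None
        assert res.alpha1 is not None

    def test_alpha1_larger_for_smoother_fbm(self):
        # H = 0.2 vs H = 0.8, a few seeds: smoother surfaces score higher
        means = []
        for H in (0.2, 0.8):
            vals = [dfa2d.dfa2d(dfa2d.generate_surface(
                dfa2d.SurfaceSpec(kind="fbm", width=128, height=128,
                                  hurst=H, seed=seed))).alpha1
                    for seed in range(5)]
            means.append(np.mean(vals))
        assert means[1] > means[0]


# ---------------------------------------------------------------- properties

@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.integers(16, 40), st.integers(16, 40))
def test_fluctuation_nonnegative_and_scale_bounded(seed, M, N):
    """F(s) >= 0 at every valid scale of a random image."""
    B = np.random.default_rng(seed).uniform(0, 255, (M, N))
    s_max = min(M, N) // 4
    curve = dfa2d.fluctuation_curve(B, range(4, s_max + 1))
    assert np.all(curve.values >= 0.0)
    assert curve.scales.max() <= s_max


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    st.integers(0, 2**31 - 1),
    st.floats(0.1, 50.0),
    st.floats(-100.0, 100.0),
)
def test_fluctuation_scales_with_contrast(seed, a, c):
    """F(aB + c) = |a| F(B): mean-centering kills c, linearity pulls out a."""
    B = np.random.default_rng(seed).uniform(0, 255, (32, 32))
    base = dfa2d.fluctuation(dfa2d.integrate_2d(B), 4)
    scaled = dfa2d.fluctuation(dfa2d.integrate_2d(a * B + c), 4)
    assert scaled == pytest.approx(abs(a) * base, rel=1e-9, abs=1e-9)
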