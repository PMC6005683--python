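"""Core numerics: autocorrelation, profiles, spectra and extremum location."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myofq import (
    ACFMap,
    Image2D,
    Profile1D,
    autocorrelate_2d,
    axis_profile,
    dominant_peak,
    first_local_minimum,
    horizontal_power_spectrum,
    radial_average,
)
from myofq.core_signals import parabolic_vertex_offset
from myofq.errors import BandError, DegenerateInputError, NoMinimumError


def direct_circular_acf(pixels: np.ndarray) -> np.ndarray:
    """Independent oracle: O(lags x pixels) sliding-lag sum with wrap-around."""
    x = pixels - pixels.mean()
    rows, cols = x.shape
    out = np.empty((rows, cols))
    for di in range(rows):
        for dj in range(cols):
            out[di, dj] = np.sum(x * np.roll(np.roll(x, -di, axis=0), -dj, axis=1))
    out /= out[0, 0]
    return np.fft.fftshift(out)


def random_image(seed: int, shape=(16, 16)) -> Image2D:
    rng = np.random.default_rng(seed)
    return Image2D(rng.uniform(0.0, 1.0, shape), pixel_size_um=0.05)


class TestAutocorrelate2D:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_direct_sliding_lag_oracle(self, seed):
        img = random_image(seed)
        fft_acf = autocorrelate_2d(img).values
        assert np.abs(fft_acf - direct_circular_acf(img.pixels)).max() < 1e-8

    def test_cosine_acf_is_cosine_of_same_period(self, cosine_image):
        acf = autocorrelate_2d(cosine_image)
        r0, c0 = acf.center
        central_row = acf.values[r0]
        lags = np.arange(64) - c0
        expected = np.cos(2 * np.pi * lags / 16.0)
        assert np.abs(central_row - expected).max() < 1e-6
        assert acf.values[r0, c0] == pytest.approx(1.0, abs=1e-12)
        assert acf.values[r0, c0 + 8] == pytest.approx(-1.0, abs=1e-6)

    def test_constant_image_rejected(self):
        img = Image2D(np.full((32, 32), 7.0), pixel_size_um=0.05)
        with pytest.raises(DegenerateInputError):
            autocorrelate_2d(img)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_and_unit_zero_lag(self, seed):
        acf = autocorrelate_2d(random_image(seed, shape=(17, 24)))
        r0, c0 = acf.center
        assert acf.values[r0, c0] == pytest.approx(1.0, abs=1e-12)
        assert np.abs(acf.values).max() <= 1.0 + 1e-9
        rows, cols = acf.shape
        for dr, dc in [(1, 0), (0, 1), (3, 5), (-2, 4), (7, -3)]:
            a = acf.values[r0 + dr, c0 + dc]
            b = acf.values[r0 - dr, c0 - dc]
            assert a == pytest.approx(b, abs=1e-9)

    @given(seed=st.integers(0, 10_000), a=st.floats(0.1, 50.0), b=st.floats(0.0, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_affine_intensity_invariance(self, seed, a, b):
        img = random_image(seed)
        scaled = Image2D(a * img.pixels + b, img.pixel_size_um)
        d = autocorrelate_2d(img).values - autocorrelate_2d(scaled).values
        assert np.abs(d).max() < 1e-9


class TestRadialAverage:
    def test_gaussian_acf_profile_matches_binning_oracle_and_analytic(self):
        sigma = 5.0
        n = 65
        y, x = np.mgrid[:n, :n] - n // 2
        r = np.hypot(x, y)
        values = np.exp(-(r**2) / (2 * sigma**2))
        prof = radial_average(ACFMap(values=values, pixel_size_um=0.05))
        # independent oracle: explicit per-pixel distance binning
        oracle, mean_radius = [], []
        for k in range(len(prof)):
            sel = (r >= k) & (r < k + 1)
            if sel.any():
                oracle.append(values[sel].mean())
                mean_radius.append(r[sel].mean())
        assert np.allclose(prof.values, oracle, atol=1e-12)
        # analytic check at each bin's mean pixel radius (the discrete radii
        # inside a 1 px annulus are not centred on the nominal bin centre)
        mean_radius = np.array(mean_radius)
        inner = mean_radius <= 3 * sigma
        analytic = np.exp(-(mean_radius[inner] ** 2) / (2 * sigma**2))
        rel = np.abs(np.array(oracle)[inner] - analytic) / analytic
        assert rel.max() < 0.02

    def test_delta_acf(self):
        n = 33
        values = np.zeros((n, n))
        values[n // 2, n // 2] = 1.0
        prof = radial_average(ACFMap(values=values, pixel_size_um=0.05))
        assert prof.values[0] == pytest.approx(1.0)
        assert np.abs(prof.values[1:]).max() == 0.0

    def test_rotation_90_leaves_radial_profile_unchanged(self):
        img = random_image(3, shape=(64, 64))
        rot = Image2D(np.rot90(img.pixels).copy(), img.pixel_size_um)
        p1 = radial_average(autocorrelate_2d(img))
        p2 = radial_average(autocorrelate_2d(rot))
        assert np.abs(p1.values - p2.values).max() < 1e-9

    def test_bin_width_floor(self):
        acf = autocorrelate_2d(random_image(0))
        with pytest.raises(ValueError):
            radial_average(acf, bin_width_px=0.25)


class TestAxisProfile:
    def test_stripe_acf_first_vertical_minimum_at_half_period(self, stripe_image):
        acf = autocorrelate_2d(stripe_image)
        prof = axis_profile(acf, "vertical")
        lag = first_local_minimum(prof)
        assert lag == pytest.approx(10 * 0.05, abs=0.05)  # half the 20 px period

    def test_separable_acf_vertical_slice(self):
        n = 32
        fx = np.cos(2 * np.pi * np.arange(n) / 16.0)
        gy = np.exp(-((np.arange(n) - n // 2) ** 2) / 50.0)
        values = gy[:, None] * np.roll(fx, n // 2)[None, :]
        acf = ACFMap(values=values, pixel_size_um=0.1)
        prof = axis_profile(acf, "vertical")
        f0 = np.roll(fx, n // 2)[n // 2]
        assert np.allclose(prof.values, gy[n // 2 :] * f0)

    @pytest.mark.parametrize("rows", [16, 17, 33, 64])
    def test_profile_length_is_ceil_half(self, rows):
        img = random_image(1, shape=(rows, 20))
        prof = axis_profile(autocorrelate_2d(img), "vertical")
        assert len(prof) == -(-rows // 2)


class TestHorizontalPowerSpectrum:
    def test_integer_period_cosine_concentrates_in_one_bin(self):
        x = np.arange(64)
        img = Image2D(
            np.tile(1.0 + np.cos(2 * np.pi * x / 32.0), (256, 1)), pixel_size_um=0.05
        )
        spec = horizontal_power_spectrum(img, window="none")
        k = int(np.argmax(spec.values))
        assert spec.axis[k] == pytest.approx(1.0 / (32 * 0.05), rel=1e-9)
        others = np.delete(spec.values, k)
        assert others.max() < 1e-6 * spec.values[k]
        assert spec.values[k] / spec.values.sum() > 0.999

    def test_noninteger_period_with_hann_within_one_bin(self):
        x = np.arange(64)
        img = Image2D(
            np.tile(1.0 + np.cos(2 * np.pi * x / 30.0), (256, 1)), pixel_size_um=0.05
        )
        spec = horizontal_power_spectrum(img, window="hann")
        k = int(np.argmax(spec.values))
        df = spec.axis[1] - spec.axis[0]
        assert abs(spec.axis[k] - 1.0 / (30 * 0.05)) <= df + 1e-12

    def test_matches_direct_sum_dft_oracle(self):
        img = random_image(11, shape=(16, 16))
        spec = horizontal_power_spectrum(img, window="none")
        x = img.pixels - img.pixels.mean()
        n = 16
        j, k = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        dft = np.exp(-2j * np.pi * j * k / n)  # naive DFT matrix
        full = dft @ (x @ dft)
        power = np.abs(full) ** 2
        oracle = power[:, 1 : n // 2 + 1].mean(axis=0)
        assert np.allclose(spec.values, oracle, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_white_noise_has_no_dominant_bin(self, seed):
        rng = np.random.default_rng(seed)
        img = Image2D(rng.uniform(0, 1, (64, 64)), pixel_size_um=0.05)
        spec = horizontal_power_spectrum(img, window="none")
        assert spec.values.max() < 5 * np.median(spec.values)

    def test_constant_image_rejected(self):
        img = Image2D(np.full((32, 32), 3.0), pixel_size_um=0.05)
        with pytest.raises(DegenerateInputError):
            horizontal_power_spectrum(img)


class TestScaleEquivariance:
    """Multiplying the pixel size by c scales lags by c and frequencies by 1/c."""

    def test_lag_and_frequency_axes_scale(self):
        img1 = random_image(5, shape=(32, 32))
        img2 = Image2D(img1.pixels, pixel_size_um=img1.pixel_size_um * 3.0)
        p1 = axis_profile(autocorrelate_2d(img1), "vertical")
        p2 = axis_profile(autocorrelate_2d(img2), "vertical")
        assert np.allclose(p2.axis, 3.0 * p1.axis)
        assert np.allclose(p2.values, p1.values)
        s1 = horizontal_power_spectrum(img1)
        s2 = horizontal_power_spectrum(img2)
        assert np.allclose(s2.axis, s1.axis / 3.0)
        assert np.allclose(s2.values, s1.values)


class TestFirstLocalMinimum:
    def test_cosine_minimum_at_half_period(self):
        r = np.arange(0.0, 2.0, 0.05)
        prof = Profile1D(axis=r, values=np.cos(2 * np.pi * r / 1.0), kind="radial_acf")
        assert first_local_minimum(prof) == pytest.approx(0.5, abs=0.025)

    def test_monotone_profile_raises(self):
        r = np.arange(0.0, 2.0, 0.05)
        prof = Profile1D(axis=r, values=np.exp(-r), kind="radial_acf")
        with pytest.raises(NoMinimumError):
            first_local_minimum(prof)

    def test_parabolic_vertex_closed_form(self):
        # vertex of the parabola through (−1, 1.0), (0, 0.2), (1, 0.4)
        assert parabolic_vertex_offset(1.0, 0.2, 0.4) == pytest.approx(0.3)
        # cross-check against a dense quadratic fit
        coeffs = np.polyfit([-1, 0, 1], [1.0, 0.2, 0.4], 2)
        assert -coeffs[1] / (2 * coeffs[0]) == pytest.approx(0.3)

    def test_smoothing_suppresses_single_sample_glitch(self):
        r = np.arange(0.0, 3.0, 0.05)
        v = np.cos(2 * np.pi * r / 2.0)
        v[4] -= 0.4  # spurious dip well before the true minimum at 1.0
        prof = Profile1D(axis=r, values=v, kind="radial_acf")
        raw = first_local_minimum(prof, smooth_halfwidth=0)
        smoothed = first_local_minimum(prof, smooth_halfwidth=2)
        assert raw < 0.5
        assert smoothed == pytest.approx(1.0, abs=0.1)


class TestDominantPeak:
    def _tone_spectrum(self, f0, n=64, df=0.015625):
        ax = df * np.arange(1, n + 1)
        vals = np.full(n, 1e-6)
        k = int(round(f0 / df)) - 1
        vals[k] = 1.0
        return Profile1D(axis=ax, values=vals, kind="horizontal_spectrum")

    def test_single_tone_located(self):
        spec = self._tone_spectrum(0.3125)
        pk = dominant_peak(spec, (0.2, 1.0))
        assert abs(pk.frequency - 0.3125) <= spec.axis[1] - spec.axis[0]
        assert pk.prominence > 100

    def test_band_restriction_ignores_stronger_out_of_band_tone(self):
        spec = self._tone_spectrum(0.3125)
        vals = spec.values.copy()
        vals[2] = 10.0  # strong tone below the band
        spec2 = Profile1D(axis=spec.axis, values=vals, kind="horizontal_spectrum")
        pk = dominant_peak(spec2, (0.2, 1.0))
        assert abs(pk.frequency - 0.3125) <= spec.axis[1] - spec.axis[0]

    def test_empty_band_raises(self):
        spec = self._tone_spectrum(0.3125)
        with pytest.raises(BandError):
            dominant_peak(spec, (10.0, 20.0))
        with pytest.raises(BandError):
            dominant_peak(spec, (1.0, 0.2))

    def test_band_edge_peak_flagged(self):
        spec = self._tone_spectrum(0.3125)
        pk = dominant_peak(spec, (0.3125, 1.0))
        assert pk.on_band_edge

    def test_noisy_striation_phantom_peak_within_one_percent(self, early_lengthwise):
        img, truth = early_lengthwise
        spec = horizontal_power_spectrum(img)
        pk = dominant_peak(spec, (0.2, 1.0))
        assert pk.frequency == pytest.approx(0.5, rel=0.01)
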