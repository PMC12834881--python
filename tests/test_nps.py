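"""NPS estimator checks: detrending, Parseval consistency, radial
reduction, scalar metrics, and ROI-size invariance of the normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ctiq
from ctiq import NoiseModel, PhantomSpec
from ctiq.nps import (
    Nps2D,
    compute_nps2d,
    detrend_roi,
    noise_metrics,
    radial_average,
    ring_layout,
)
from ctiq.stack import ImageStack


def _grid(n):
    c = np.arange(n) - (n - 1) / 2.0
    return np.meshgrid(c, c)


class TestDetrend:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(coeffs=st.lists(st.floats(-50, 50), min_size=6, max_size=6))
    def test_second_order_surface_removed_exactly(self, coeffs):
        x, y = _grid(32)
        surface = (
            coeffs[0] + coeffs[1] * x + coeffs[2] * y
            + coeffs[3] * x**2 + coeffs[4] * x * y + coeffs[5] * y**2
        )
        resid = detrend_roi(surface)
        assert np.max(np.abs(resid)) <= 1e-9 * max(np.max(np.abs(surface)), 1.0)

    def test_constant_roi_gives_zero_residual(self):
        assert np.allclose(detrend_roi(np.full((16, 16), 40.0)), 0.0)

    def test_residual_mean_is_zero(self):
        rng = np.random.default_rng(0)
        resid = detrend_roi(rng.normal(size=(24, 24)))
        assert abs(resid.mean()) < 1e-12

    def test_residual_variance_loses_six_degrees_of_freedom(self):
        # brute-force Monte Carlo: polynomial + white noise sigma=5 over 500 ROIs
        rng = np.random.default_rng(1)
        n = 24
        x, y = _grid(n)
        surface = 3.0 + 0.5 * x - 0.2 * y + 0.01 * x**2
        total = 0.0
        n_rois = 500
        for _ in range(n_rois):
            roi = surface + rng.normal(scale=5.0, size=(n, n))
            total += np.mean(detrend_roi(roi) ** 2)
        expected = 25.0 * (1.0 - 6.0 / (n * n))
        assert total / n_rois == pytest.approx(expected, rel=0.015)

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError):
            detrend_roi(np.ones((1, 1)))
        with pytest.raises(ValueError):
            detrend_roi(np.ones((4, 4)))


class TestCompute2D:
    def test_parseval_white_noise_integrates_to_variance(self, white_noise_stack_protocol):
        _, stack = white_noise_stack_protocol
        layout = ring_layout((512, 512), roi_size=104, roi_count=8)
        nps2d = compute_nps2d(stack, layout)
        df = nps2d.grid_step
        integral = nps2d.values.sum() * df * df
        assert integral == pytest.approx(100.0, rel=0.03)

    def test_constant_stack_gives_zero_spectrum(self):
        stack = ImageStack(np.full((3, 128, 128), 55.0), pixel_spacing=0.5)
        layout = ring_layout((128, 128), roi_size=32, roi_count=4)
        nps2d = compute_nps2d(stack, layout)
        assert np.allclose(nps2d.values, 0.0, atol=1e-18)

    def test_point_reflection_symmetry_about_dc(self, white_noise_stack_protocol):
        _, stack = white_noise_stack_protocol
        layout = ring_layout((512, 512), roi_size=64, roi_count=4)
        v = compute_nps2d(stack, layout).values
        # real input -> |DFT|^2 Hermitian: value at k equals value at -k
        flipped = np.roll(np.flip(v), (1, 1), axis=(0, 1))
        assert np.allclose(v, flipped, rtol=1e-10)

    def test_roi_size_invariance_of_normalisation(self, white_noise_stack_protocol):
        _, stack = white_noise_stack_protocol
        m_small = noise_metrics(
            compute_nps2d(stack, ring_layout((512, 512), roi_size=64, roi_count=8))
        )
        m_large = noise_metrics(
            compute_nps2d(stack, ring_layout((512, 512), roi_size=104, roi_count=8))
        )
        assert m_small.noise_magnitude == pytest.approx(
            m_large.noise_magnitude, rel=0.02
        )

    def test_out_of_bounds_roi_rejected(self):
        stack = ImageStack(np.zeros((1, 64, 64)), pixel_spacing=0.5)
        layout = ctiq.RoiLayout(roi_size=32, roi_origins=[(48, 0)])
        with pytest.raises(ValueError):
            compute_nps2d(stack, layout)

    def test_oracle_equivalence_with_sample_std(self, white_noise_stack_protocol):
        _, stack = white_noise_stack_protocol
        layout = ring_layout((512, 512), roi_size=104, roi_count=8)
        metrics = noise_metrics(compute_nps2d(stack, layout))
        # direct estimate of the same variance from the detrended pixels
        resids = []
        for s in range(stack.n_slices):
            for r0, c0 in layout.roi_origins:
                roi = stack.voxels[s, r0 : r0 + 104, c0 : c0 + 104]
                resids.append(detrend_roi(roi).ravel())
        sample_std = np.std(np.concatenate(resids))
        assert metrics.noise_magnitude == pytest.approx(sample_std, rel=0.01)


def _synthetic_nps2d(radial_fn, n=64, dx=0.5):
    freq = np.fft.fftshift(np.fft.fftfreq(n, d=dx))
    fx, fy = np.meshgrid(freq, freq)
    return Nps2D(
        values=radial_fn(np.hypot(fx, fy)),
        freq_x=freq, freq_y=freq, pixel_spacing=dx,
    )


class TestRadialAverage:
    def test_flat_spectrum_gives_flat_profile(self):
        nps2d = _synthetic_nps2d(lambda r: np.full_like(r, 3.5))
        nps1d = radial_average(nps2d)
        assert np.allclose(nps1d.values, 3.5, rtol=1e-12)
        assert nps1d.freq[-1] <= nps2d.nyquist + 1e-12

    def test_dc_spike_concentrates_in_first_bin(self):
        def spike(r):
            v = np.zeros_like(r)
            v[r == 0] = 7.0
            return v

        nps1d = radial_average(_synthetic_nps2d(spike))
        assert nps1d.values[0] > 0
        assert np.allclose(nps1d.values[1:], 0.0)

    def test_reproduces_generating_radial_curve(self):
        curve = lambda r: np.exp(-((r - 0.4) ** 2) / (2 * 0.1**2))
        nps2d = _synthetic_nps2d(curve, n=128, dx=0.5)
        nps1d = radial_average(nps2d)
        # each annular mean lies within the curve's range over +/- one bin width
        b = nps1d.bin_width
        samples = np.stack([curve(nps1d.freq + s) for s in (-b, -b / 2, 0, b / 2, b)])
        assert np.all(nps1d.values >= samples.min(axis=0) - 1e-12)
        assert np.all(nps1d.values <= samples.max(axis=0) + 1e-12)


class TestMetrics:
    def test_white_noise_magnitude_recovered(self, white_noise_stack_protocol):
        _, stack = white_noise_stack_protocol
        layout = ring_layout((512, 512), roi_size=104, roi_count=8)
        _, _, metrics = ctiq.analyze_noise(stack, layout)
        assert metrics.noise_magnitude == pytest.approx(10.0, rel=0.03)

    def test_flat_profile_f_av_matches_binning_oracle(self):
        nps2d = _synthetic_nps2d(lambda r: np.ones_like(r))
        nps1d = radial_average(nps2d)
        metrics = noise_metrics(nps2d, nps1d)
        # oracle: the same weighted mean computed directly from the bins
        expected = float(np.sum(nps1d.freq * nps1d.values) / np.sum(nps1d.values))
        assert metrics.f_av == pytest.approx(expected, rel=1e-12)
        assert metrics.f_av == pytest.approx(nps2d.nyquist / 2, rel=0.15)

    def test_scaling_homogeneity(self):
        nps2d = _synthetic_nps2d(lambda r: np.exp(-r))
        m1 = noise_metrics(nps2d)
        scaled = Nps2D(
            values=4.0 * nps2d.values, freq_x=nps2d.freq_x,
            freq_y=nps2d.freq_y, pixel_spacing=nps2d.pixel_spacing,
        )
        m4 = noise_metrics(scaled)
        assert m4.noise_magnitude == pytest.approx(2.0 * m1.noise_magnitude, rel=1e-12)
        assert m4.f_av == pytest.approx(m1.f_av, rel=1e-12)
        assert m4.nps1d_peak == pytest.approx(4.0 * m1.nps1d_peak, rel=1e-12)

    def test_all_zero_spectrum_returns_missing_f_av(self):
        nps2d = _synthetic_nps2d(lambda r: np.zeros_like(r))
        metrics = noise_metrics(nps2d)
        assert metrics.f_av is None
        assert metrics.noise_magnitude == 0.0

    def test_f_av_increases_when_spectrum_shifts_up(self):
        f_avs = []
        for center in (0.15, 0.25, 0.35):
            spec = PhantomSpec(
                matrix_size=128, fov=80, slice_count=20,
                noise_model=NoiseModel(
                    magnitude=10.0, spectrum_shape="gaussian_bandpass",
                    shape_params={"center": center, "width": 0.05},
                ),
                seed=50,
            )
            stack = ctiq.make_correlated_noise(spec)
            _, _, metrics = ctiq.analyze_noise(
                stack, ring_layout((128, 128), roi_size=48, roi_count=4)
            )
            f_avs.append(metrics.f_av)
        assert f_avs[0] < f_avs[1] < f_avs[2]

    def test_bandpass_peak_frequency_recovered(self, bandpass_stack_protocol):
        spec, stack = bandpass_stack_protocol
        layout = ring_layout((512, 512), roi_size=104, roi_count=8)
        _, nps1d, _ = ctiq.analyze_noise(stack, layout)
        peak_f = nps1d.freq[np.argmax(nps1d.values)]
        assert peak_f == pytest.approx(0.2, abs=nps1d.bin_width)
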