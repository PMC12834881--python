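"""The synthetic generator must deliver the statistics it promises:
exact variance, exact spectrum shape, stationarity and determinism —
these are the oracles every downstream estimator is validated against."""

import numpy as np
import pytest
from scipy import stats

import ctiq
from ctiq import InvalidSpecError, NoiseModel, PhantomSpec
from ctiq.nps import detrend_roi

from conftest import PIXEL_NR, PIXEL_SR


def test_white_noise_sample_std_matches_requested_magnitude(white_noise_stack_protocol):
    spec, stack = white_noise_stack_protocol
    # detrend a large central region exactly as the NPS chain would
    resid = np.concatenate(
        [detrend_roi(s[128:384, 128:384]).ravel() for s in stack.voxels[:10]]
    )
    assert np.std(stack.voxels) == pytest.approx(10.0, rel=0.02)
    assert np.std(resid) == pytest.approx(10.0, rel=0.02)


def test_zero_magnitude_yields_shading_only():
    shading = (5.0, 0.0, 0.0, 2.0, 0.0, 2.0)
    spec = PhantomSpec(
        matrix_size=64, fov=40, slice_count=3,
        noise_model=NoiseModel(magnitude=0.0, shading=shading), seed=0,
    )
    stack = ctiq.make_correlated_noise(spec)
    assert np.all(stack.voxels[0] == stack.voxels[1])
    # pure 2nd-order surface: detrending must annihilate it
    assert np.allclose(detrend_roi(stack.voxels[0]), 0.0, atol=1e-9)


def test_bandpass_empirical_spectrum_peaks_at_requested_center():
    spec = PhantomSpec(
        matrix_size=256, fov=160, slice_count=40,
        noise_model=NoiseModel(
            magnitude=10.0, spectrum_shape="gaussian_bandpass",
            shape_params={"center": 0.2, "width": 0.05},
        ),
        seed=7,
    )
    stack = ctiq.make_correlated_noise(spec)
    # independent oracle: radially average raw whole-slice periodograms
    dx = spec.pixel_spacing
    accum = np.zeros((256, 256))
    for s in stack.voxels:
        accum += np.abs(np.fft.fft2(s - s.mean())) ** 2
    f1 = np.fft.fftfreq(256, d=dx)
    fr = np.hypot(*np.meshgrid(f1, f1)).ravel()
    df = f1[1]
    idx = np.floor(fr / df + 0.5).astype(int)
    radial = np.bincount(idx, weights=accum.ravel()) / np.maximum(
        np.bincount(idx), 1
    )
    peak_f = np.argmax(radial) * df
    # within one frequency bin (inclusive)
    assert abs(peak_f - 0.2) <= df * (1 + 1e-9)


def test_expected_spectrum_fidelity_against_generator_truth(bandpass_stack_protocol):
    spec, stack = bandpass_stack_protocol
    layout = ctiq.ring_layout((512, 512), roi_size=104, roi_count=8)
    _, nps1d, _ = ctiq.analyze_noise(stack, layout)
    truth = ctiq.true_nps_radial(spec, nps1d.freq)
    # DC bin excluded: a detrended periodogram cannot estimate it by construction
    err = np.linalg.norm(nps1d.values[1:] - truth[1:]) / np.linalg.norm(truth[1:])
    assert err < 0.05


def test_seed_determinism_bit_identical():
    kwargs = dict(
        matrix_size=128, fov=80, slice_count=4,
        noise_model=NoiseModel(magnitude=12.0), seed=42,
    )
    a = ctiq.make_correlated_noise(PhantomSpec(**kwargs))
    b = ctiq.make_correlated_noise(PhantomSpec(**kwargs))
    assert np.array_equal(a.voxels, b.voxels)


def test_stationarity_quadrant_variances_homogeneous():
    rejections = 0
    for seed in range(5):
        spec = PhantomSpec(
            matrix_size=128, fov=80, slice_count=1,
            noise_model=NoiseModel(magnitude=10.0), seed=200 + seed,
        )
        img = ctiq.make_correlated_noise(spec).voxels[0]
        quadrants = [img[:64, :64], img[:64, 64:], img[64:, :64], img[64:, 64:]]
        _, p = stats.bartlett(*[q.ravel() for q in quadrants])
        if p < 0.01:
            rejections += 1
    assert rejections <= 1


@pytest.mark.parametrize(
    "bad_kwargs",
    [
        {"matrix_size": 0},
        {"matrix_size": 63},
        {"fov": -1.0},
    ],
)
def test_invalid_geometry_rejected(bad_kwargs):
    kwargs = dict(
        matrix_size=64, fov=40.0, slice_count=1,
        noise_model=NoiseModel(magnitude=1.0), seed=0,
    )
    kwargs.update(bad_kwargs)
    with pytest.raises(InvalidSpecError):
        PhantomSpec(**kwargs)


def test_negative_tabulated_spectrum_rejected():
    with pytest.raises(InvalidSpecError):
        NoiseModel(
            magnitude=1.0, spectrum_shape="tabulated",
            shape_params={"freq": [0.0, 0.5], "values": [1.0, -0.1]},
        )


class TestInsertStack:
    def test_noiseless_sharp_disk_has_exact_plateaus(self):
        spec = PhantomSpec(
            matrix_size=128, fov=80, slice_count=1, background_hu=40.0,
            noise_model=NoiseModel(magnitude=0.0), seed=0,
            insert_diameter=30.0, insert_contrast=100.0, psf_sigma=0.0,
        )
        stack = ctiq.make_insert_stack(spec)
        px, py = stack.pixel_coords_mm()
        r = np.hypot(px, py)
        assert np.allclose(stack.voxels[0][r < 12.0], 140.0)
        assert np.allclose(stack.voxels[0][r > 18.0], 40.0)

    def test_measured_roi_contrast_matches_spec(self):
        spec = PhantomSpec(
            matrix_size=256, fov=80, slice_count=20,
            noise_model=NoiseModel(magnitude=10.0), seed=9,
            insert_diameter=25.0, insert_contrast=350.0, psf_sigma=0.4,
        )
        stack = ctiq.make_insert_stack(spec)
        px, py = stack.pixel_coords_mm()
        r = np.hypot(px, py)
        interior = stack.voxels[:, r < 8.0].mean()
        exterior = stack.voxels[:, (r > 18.0) & (r < 30.0)].mean()
        # noise-limited tolerance: sem over the pooled ROI pixels is << 1 HU
        assert interior - exterior == pytest.approx(350.0, abs=1.0)

    def test_insert_extending_beyond_image_rejected(self):
        spec = PhantomSpec(
            matrix_size=64, fov=40, slice_count=1,
            noise_model=NoiseModel(magnitude=0.0), seed=0,
            insert_diameter=39.0, insert_contrast=100.0,
            insert_center=(10.0, 0.0),
        )
        with pytest.raises(InvalidSpecError):
            ctiq.make_insert_stack(spec)


class TestProtocolSeries:
    @pytest.mark.parametrize(
        "matrix,expected", [(512, PIXEL_NR), (1024, PIXEL_SR)]
    )
    def test_protocol_pixel_spacing(self, matrix, expected):
        homog, insert = ctiq.make_protocol_series(
            12.7, "NR-DLR", 2, matrix_size=matrix,
            slice_count_homogeneous=1, slice_count_insert=1, seed=1,
        )
        assert homog.pixel_spacing == pytest.approx(expected, abs=1e-4)
        assert insert.pixel_spacing == pytest.approx(expected, abs=1e-4)
        assert homog.meta["dose_mgy"] == 12.7

    def test_noise_scales_as_inverse_sqrt_dose(self):
        cal = NoiseModel(magnitude=10.0)
        low, _ = ctiq.make_protocol_series(
            3.0, "NR-DLR", 1, matrix_size=256, noise_calibration=cal,
            fov=160.0, slice_count_homogeneous=20, slice_count_insert=1, seed=3,
        )
        high, _ = ctiq.make_protocol_series(
            12.7, "NR-DLR", 1, matrix_size=256, noise_calibration=cal,
            fov=160.0, slice_count_homogeneous=20, slice_count_insert=1, seed=3,
        )
        ratio = np.std(high.voxels) / np.std(low.voxels)
        assert ratio == pytest.approx(np.sqrt(3.0 / 12.7), rel=0.03)

    def test_unknown_labels_rejected_in_strict_mode(self):
        with pytest.raises(KeyError):
            ctiq.make_protocol_series(12.7, "UNKNOWN-ALGO", 1, matrix_size=256, seed=0)
        with pytest.raises(KeyError):
            ctiq.make_protocol_series(4.2, "NR-DLR", 1, matrix_size=256, seed=0)
        # non-strict mode accepts arbitrary positive doses
        ctiq.make_protocol_series(
            4.2, "NR-DLR", 1, matrix_size=128, fov=80.0, strict=False,
            slice_count_homogeneous=1, slice_count_insert=1, seed=0,
        )
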