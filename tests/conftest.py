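import numpy as np
import pytest

from ctiq import NoiseModel, PhantomSpec, make_correlated_noise, make_insert_stack

# pixel spacings of the two emulated reconstruction protocols (320.3 mm fov)
PIXEL_NR = 320.3 / 512
PIXEL_SR = 320.3 / 1024


@pytest.fixture(scope="session")
def white_noise_stack_protocol():
    """50 slices of white noise, sigma 10 HU, at the 512-matrix protocol size."""
    spec = PhantomSpec(
        matrix_size=512, fov=320.3, slice_count=50,
        noise_model=NoiseModel(magnitude=10.0), seed=101,
    )
    return spec, make_correlated_noise(spec)


@pytest.fixture(scope="session")
def bandpass_stack_protocol():
    """Correlated noise with a broad lobe at 0.2 mm^-1, protocol averaging scale."""
    spec = PhantomSpec(
        matrix_size=512, fov=320.3, slice_count=50,
        noise_model=NoiseModel(
            magnitude=10.0, spectrum_shape="gaussian_bandpass",
            shape_params={"center": 0.2, "width": 0.1},
        ),
        seed=102,
    )
    return spec, make_correlated_noise(spec)


def insert_stack(psf_sigma, noise_hu, contrast=350.0, slices=100, seed=103, matrix=256):
    """Cylindrical insert at the 1024-matrix protocol pixel size, reduced window."""
    spec = PhantomSpec(
        matrix_size=matrix, fov=matrix * PIXEL_SR, slice_count=slices,
        noise_model=NoiseModel(magnitude=noise_hu), seed=seed,
        insert_diameter=25.0, insert_contrast=contrast, psf_sigma=psf_sigma,
    )
    return spec, make_insert_stack(spec)


@pytest.fixture(scope="session")
def blurred_insert_stack():
    """100-slice insert, Gaussian PSF sigma 0.5 mm, moderate noise."""
    return insert_stack(psf_sigma=0.5, noise_hu=10.0)


@pytest.fixture(scope="session")
def reduced_run():
    """Full synthetic study at quarter scale: 2 algorithms x 3 levels x 3 doses."""
    import ctiq

    cfg = ctiq.RunConfig(
        scale=0.25, slices_homogeneous=40, slices_insert=30, seed=13,
        dprime_grid_points=256,
    )
    return ctiq.run_pipeline(cfg), cfg
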