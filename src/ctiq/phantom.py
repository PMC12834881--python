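"""Synthetic phantom-image generator with analytically known noise and blur.

Stands in for axial acquisitions of an image-quality phantom (homogeneous
section for noise analysis, cylindrical insert section for edge analysis).
Noise is generated by spectral shaping: the FFT of unit white noise is
multiplied by the square root of the target power spectrum and transformed
back, so the true noise power spectrum (NPS) of every generated stack is
known in closed form and serves as an exact oracle for the estimators.

Inserts are rasterised with area-weighted 8x supersampling at the edge (the
sub-pixel edge position is precisely what the circular-edge technique
measures) and blurred with a Gaussian point spread function, so the true
transfer function is the analytic Gaussian MTF times the pixel aperture.

Slices are statistically independent: axial slices are analysed
independently downstream and z-correlation is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy import ndimage

from .stack import ImageStack

__all__ = [
    "NoiseModel",
    "PhantomSpec",
    "InvalidSpecError",
    "make_correlated_noise",
    "make_insert_stack",
    "true_nps2d",
    "true_nps_radial",
    "make_protocol_series",
    "series_preset",
    "PROTOCOL_DOSES_MGY",
    "PROTOCOL_FOV_MM",
    "REFERENCE_DOSE_MGY",
]

#: The three CTDIvol dose levels of the emulated protocol, mGy.
PROTOCOL_DOSES_MGY = (3.0, 5.9, 12.7)
#: Reconstruction field of view, mm.
PROTOCOL_FOV_MM = 320.3
#: Dose at which noise-model calibrations are defined, mGy.
REFERENCE_DOSE_MGY = 12.7

# full width at half maximum of a unit-sigma Gaussian
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


class InvalidSpecError(ValueError):
    """Raised when a phantom specification is geometrically or physically invalid."""


@dataclass
class NoiseModel:
    """Stationary correlated-noise description.

    Parameters
    ----------
    magnitude
        Target standard deviation of the noise field, HU. The shaped
        spectrum is normalised so the per-pixel variance equals
        ``magnitude**2`` exactly in expectation.
    spectrum_shape
        One of ``"white"``, ``"gaussian_bandpass"`` (radial Gaussian bump,
        params ``center`` and ``width`` in mm^-1) or ``"tabulated"``
        (params ``freq`` and ``values``: a nonnegative radial curve,
        linearly interpolated, zero beyond the last tabulated frequency).
    shape_params
        Parameters of the chosen shape.
    shading
        Optional 6-vector ``(c0, cx, cy, cxx, cxy, cyy)`` of a 2nd-order
        polynomial background in HU, evaluated on coordinates normalised to
        [-1, 1] across the field of view and added after the noise. Emulates
        the slowly varying background that the NPS detrending step removes.
    """

    magnitude: float
    spectrum_shape: str = "white"
    shape_params: dict[str, Any] = field(default_factory=dict)
    shading: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise InvalidSpecError("noise magnitude must be >= 0")
        if self.spectrum_shape not in ("white", "gaussian_bandpass", "tabulated"):
            raise InvalidSpecError(
                f"unknown spectrum_shape {self.spectrum_shape!r}"
            )
        if self.spectrum_shape == "tabulated":
            vals = np.asarray(self.shape_params.get("values", []), dtype=float)
            if vals.size == 0:
                raise InvalidSpecError("tabulated spectrum needs 'freq' and 'values'")
            if np.any(vals < 0):
                raise InvalidSpecError("tabulated spectrum values must be nonnegative")

    def radial_shape(self, f: np.ndarray) -> np.ndarray:
        """Unnormalised spectrum shape evaluated at radial frequency ``f`` (mm^-1)."""
        f = np.asarray(f, dtype=float)
        if self.spectrum_shape == "white":
            return np.ones_like(f)
        if self.spectrum_shape == "gaussian_bandpass":
            center = float(self.shape_params["center"])
            width = float(self.shape_params["width"])
            return np.exp(-((f - center) ** 2) / (2.0 * width**2))
        freq = np.asarray(self.shape_params["freq"], dtype=float)
        values = np.asarray(self.shape_params["values"], dtype=float)
        return np.interp(f, freq, values, left=values[0], right=0.0)


@dataclass
class PhantomSpec:
    """Geometry and noise description of one synthetic acquisition.

    ``insert_center`` is in mm with the physical origin at the image
    centre. ``psf_sigma`` is the standard deviation of the Gaussian point
    spread function in mm; zero means an ideal (aperture-only) edge.
    """

    matrix_size: int
    fov: float
    slice_count: int
    noise_model: NoiseModel
    seed: int
    background_hu: float = 0.0
    insert_diameter: float = 25.0
    insert_contrast: float = 0.0
    insert_center: tuple[float, float] = (0.0, 0.0)
    psf_sigma: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix_size < 64 or self.matrix_size % 2 != 0:
            raise InvalidSpecError("matrix_size must be an even integer >= 64")
        if self.fov <= 0:
            raise InvalidSpecError("fov must be positive")
        if self.slice_count < 1:
            raise InvalidSpecError("slice_count must be >= 1")
        if self.psf_sigma < 0:
            raise InvalidSpecError("psf_sigma must be >= 0")

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.matrix_size


def _shaped_spectrum(spec: PhantomSpec) -> np.ndarray:
    """Discrete target spectrum S(k) with per-pixel variance = magnitude^2.

    The generated noise is ``ifft2(sqrt(S) * fft2(white))``; with iid unit
    white noise the per-pixel variance is ``mean(S)``, so S is scaled to
    make that equal ``magnitude**2``. The true NPS of the generated field is
    then ``pixel_spacing**2 * S`` on the DC-centred FFT grid.
    """
    n = spec.matrix_size
    dx = spec.pixel_spacing
    f1 = np.fft.fftfreq(n, d=dx)
    fx, fy = np.meshgrid(f1, f1)
    fr = np.hypot(fx, fy)
    s = spec.noise_model.radial_shape(fr).astype(float)
    s[0, 0] = 0.0  # mean-free noise slices
    total = s.sum()
    if total <= 0:
        if spec.noise_model.magnitude > 0:
            raise InvalidSpecError("spectrum shape is identically zero")
        return np.zeros_like(s)
    return s * (spec.noise_model.magnitude**2 * n * n / total)


def true_nps2d(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact NPS of the generated noise: DC-centred values (HU^2 mm^2) and freq axis."""
    s = _shaped_spectrum(spec)
    nps = np.fft.fftshift(s) * spec.pixel_spacing**2
    freq = np.fft.fftshift(np.fft.fftfreq(spec.matrix_size, d=spec.pixel_spacing))
    return nps, freq


def true_nps_radial(spec: PhantomSpec, f: np.ndarray) -> np.ndarray:
    """Exact radial NPS density (HU^2 mm^2) of the generated noise at frequency ``f``.

    Evaluates the same normalised spectrum the generator shapes the noise
    with, so estimators measured on any ROI grid can be compared against it.
    """
    s = _shaped_spectrum(spec)
    n = spec.matrix_size
    f1 = np.fft.fftfreq(n, d=spec.pixel_spacing)
    fx, fy = np.meshgrid(f1, f1)
    fr = np.hypot(fx, fy)
    shape_at = spec.noise_model.radial_shape(np.asarray(f, dtype=float))
    # recover the generation-grid scaling alpha = S / s
    ref = spec.noise_model.radial_shape(fr)
    ref[0, 0] = 0.0
    total = ref.sum()
    alpha = spec.noise_model.magnitude**2 * n * n / total
    return spec.pixel_spacing**2 * alpha * shape_at


def _shading_field(spec: PhantomSpec) -> np.ndarray | None:
    coeffs = spec.noise_model.shading
    if coeffs is None:
        return None
    c0, cx, cy, cxx, cxy, cyy = coeffs
    n = spec.matrix_size
    u = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0)
    ux, uy = np.meshgrid(u, u)
    return c0 + cx * ux + cy * uy + cxx * ux**2 + cxy * ux * uy + cyy * uy**2


def _noise_slices(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    amp = np.sqrt(_shaped_spectrum(spec))
    n = spec.matrix_size
    out = np.empty((spec.slice_count, n, n))
    for k in range(spec.slice_count):
        white = rng.standard_normal((n, n))
        out[k] = np.fft.ifft2(amp * np.fft.fft2(white)).real
    return out


def make_correlated_noise(spec: PhantomSpec) -> ImageStack:
    """Generate independent homogeneous noise slices with a known spectrum.

    Returns a stack whose expected 2-D NPS equals the requested shape scaled
    so the per-pixel variance is ``magnitude**2``; the optional shading
    polynomial and the background HU offset are added afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    voxels = _noise_slices(spec, rng) + spec.background_hu
    shading = _shading_field(spec)
    if shading is not None:
        voxels += shading
    meta = dict(spec.meta)
    meta.setdefault("kind", "homogeneous")
    return ImageStack(voxels, spec.pixel_spacing, meta=meta)


def _disk_coverage(spec: PhantomSpec, supersample: int = 8) -> np.ndarray:
    """Area-weighted rasterisation of the insert disk (values in [0, 1]).

    Pixels whose centre is more than one pixel away from the rim get exact
    0/1 coverage; rim pixels are subdivided ``supersample`` times per axis.
    """
    n = spec.matrix_size
    dx = spec.pixel_spacing
    radius = spec.insert_diameter / 2.0
    cx, cy = spec.insert_center
    if radius <= 0:
        raise InvalidSpecError("insert_diameter must be positive")
    if max(abs(cx), abs(cy)) + radius >= spec.fov / 2.0:
        raise InvalidSpecError("insert extends beyond the field of view")

    coords = (np.arange(n) - (n - 1) / 2.0) * dx
    px, py = np.meshgrid(coords - cx, coords - cy)
    r = np.hypot(px, py)
    coverage = (r <= radius).astype(float)

    band = np.abs(r - radius) <= dx * 1.5
    rows, cols = np.nonzero(band)
    sub = (np.arange(supersample) + 0.5) / supersample - 0.5
    sx, sy = np.meshgrid(sub * dx, sub * dx)
    for i, j in zip(rows, cols):
        rr = np.hypot(px[i, j] + sx, py[i, j] + sy)
        coverage[i, j] = np.mean(rr <= radius)
    return coverage


def make_insert_stack(spec: PhantomSpec, supersample: int = 8) -> ImageStack:
    """Generate slices of a cylindrical insert on a uniform background.

    The disk (value ``background_hu + insert_contrast`` on ``background_hu``)
    is rasterised with anti-aliased edges, convolved with the Gaussian PSF,
    and independent noise per ``noise_model`` is added to every slice.
    """
    if spec.insert_diameter >= spec.fov:
        raise InvalidSpecError("insert_diameter must be smaller than the fov")
    coverage = _disk_coverage(spec, supersample=supersample)
    if spec.psf_sigma > 0:
        coverage = ndimage.gaussian_filter(
            coverage, sigma=spec.psf_sigma / spec.pixel_spacing, mode="nearest"
        )
    base = spec.background_hu + spec.insert_contrast * coverage
    shading = _shading_field(spec)
    if shading is not None:
        base = base + shading

    rng = np.random.default_rng(spec.seed)
    voxels = base[None, :, :] + (
        _noise_slices(spec, rng)
        if spec.noise_model.magnitude > 0
        else np.zeros((spec.slice_count, spec.matrix_size, spec.matrix_size))
    )
    meta = dict(spec.meta)
    meta.setdefault("kind", "insert")
    meta.setdefault("insert_diameter_mm", spec.insert_diameter)
    meta.setdefault("insert_contrast_hu", spec.insert_contrast)
    meta.setdefault("insert_center_mm", tuple(spec.insert_center))
    meta.setdefault("psf_sigma_mm", spec.psf_sigma)
    return ImageStack(voxels, spec.pixel_spacing, meta=meta)


# ---------------------------------------------------------------------------
# Protocol-like presets
# ---------------------------------------------------------------------------

# Illustrative noise/resolution calibrations at the reference dose (12.7 mGy).
# The emulated study reports measurements, not a noise model, so these values
# only mimic the broad pattern of a normal-resolution (512^2) and a
# super-resolution (1024^2) deep-learning reconstruction across its three
# strength levels: noise magnitude (HU), the NPS-weighted mean frequency of
# the noise texture (mm^-1), and the Gaussian-equivalent PSF sigma (mm).
_PRESETS = {
    "NR-DLR": {
        "matrix": 512,
        1: {"magnitude": 12.5, "f_av": 0.23, "psf_sigma": 0.625},
        2: {"magnitude": 11.7, "f_av": 0.23, "psf_sigma": 0.605},
        3: {"magnitude": 11.3, "f_av": 0.23, "psf_sigma": 0.586},
    },
    "SR-DLR": {
        "matrix": 1024,
        1: {"magnitude": 16.0, "f_av": 0.40, "psf_sigma": 0.493},
        2: {"magnitude": 8.8, "f_av": 0.32, "psf_sigma": 0.493},
        3: {"magnitude": 6.2, "f_av": 0.28, "psf_sigma": 0.507},
    },
}
_ALGORITHM_ALIASES = {"AICE": "NR-DLR", "PIQE": "SR-DLR"}

# exponents of the empirical dose dependence of texture and sharpness
_FAV_DOSE_EXP = 0.15
_PSF_DOSE_EXP = 0.20


def _ramp_gaussian_table(f_av: float, f_max: float) -> dict[str, np.ndarray]:
    """Tabulated radial spectrum f^2 exp(-(f/b)^2) with mean frequency ``f_av``.

    For this shape the (annular-mean) NPS-weighted mean frequency is
    2 b / sqrt(pi), so b = f_av * sqrt(pi) / 2.
    """
    b = f_av * math.sqrt(math.pi) / 2.0
    freq = np.linspace(0.0, f_max, 257)
    values = freq**2 * np.exp(-((freq / b) ** 2))
    return {"freq": freq, "values": values}


def _parse_level(level_label: str | int) -> int:
    if isinstance(level_label, int):
        return level_label
    text = str(level_label).lower().replace("level-", "").replace("level", "").strip()
    return int(text)


def series_preset(
    algorithm_label: str, level_label: str | int, dose_mgy: float, nyquist: float
) -> tuple[NoiseModel, float]:
    """Resolve (noise model, psf_sigma mm) for an algorithm/level/dose preset.

    Noise magnitude scales as 1/sqrt(dose) from the reference dose; texture
    coarsens and the PSF widens at lower dose, mimicking the dose dependence
    a nonlinear reconstruction exhibits.
    """
    key = algorithm_label.upper()
    key = _ALGORITHM_ALIASES.get(key, key.upper())
    if key not in _PRESETS:
        raise KeyError(f"unknown algorithm label {algorithm_label!r}")
    level = _parse_level(level_label)
    if level not in (1, 2, 3):
        raise KeyError(f"unknown level label {level_label!r}")
    p = _PRESETS[key][level]
    rel = dose_mgy / REFERENCE_DOSE_MGY
    magnitude = p["magnitude"] / math.sqrt(rel)
    f_av = p["f_av"] * rel**_FAV_DOSE_EXP
    psf_sigma = p["psf_sigma"] / rel**_PSF_DOSE_EXP
    model = NoiseModel(
        magnitude=magnitude,
        spectrum_shape="tabulated",
        shape_params=_ramp_gaussian_table(f_av, 1.5 * nyquist),
    )
    return model, psf_sigma


def make_protocol_series(
    dose_label: float,
    algorithm_label: str,
    level_label: str | int,
    matrix_size: int,
    noise_calibration: NoiseModel | None = None,
    *,
    fov: float = PROTOCOL_FOV_MM,
    slice_count_homogeneous: int = 50,
    slice_count_insert: int = 100,
    insert_diameter: float = 25.0,
    insert_contrast: float = 350.0,
    psf_sigma: float | None = None,
    seed: int = 0,
    strict: bool = True,
) -> tuple[ImageStack, ImageStack]:
    """Generate the (homogeneous, insert) stack pair for one study condition.

    With ``noise_calibration`` given, its magnitude is taken to hold at the
    reference dose (12.7 mGy) and is scaled by ``sqrt(ref/dose)`` — the
    standard quantum-noise dose scaling. Without it, the built-in
    algorithm/level preset supplies both the noise model and the PSF width.
    In strict mode only the protocol's dose levels and known algorithm and
    level labels are accepted.
    """
    dose = float(dose_label)
    if dose <= 0:
        raise InvalidSpecError("dose must be positive")
    if strict and not any(abs(dose - d) < 1e-9 for d in PROTOCOL_DOSES_MGY):
        raise KeyError(f"dose {dose} mGy is not one of the protocol levels {PROTOCOL_DOSES_MGY}")

    pixel = fov / matrix_size
    nyquist = 1.0 / (2.0 * pixel)
    if noise_calibration is None:
        model, preset_sigma = series_preset(algorithm_label, level_label, dose, nyquist)
        if psf_sigma is None:
            psf_sigma = preset_sigma
    else:
        if strict:
            # validate labels even when the noise model is user-supplied
            series_preset(algorithm_label, level_label, dose, nyquist)
        scale = math.sqrt(REFERENCE_DOSE_MGY / dose)
        model = replace(noise_calibration, magnitude=noise_calibration.magnitude * scale)
        if psf_sigma is None:
            psf_sigma = 0.5
    meta = {
        "dose_mgy": dose,
        "algorithm": algorithm_label,
        "level": _parse_level(level_label),
    }
    homog = make_correlated_noise(
        PhantomSpec(
            matrix_size=matrix_size,
            fov=fov,
            slice_count=slice_count_homogeneous,
            noise_model=model,
            seed=seed,
            meta=dict(meta),
        )
    )
    insert = make_insert_stack(
        PhantomSpec(
            matrix_size=matrix_size,
            fov=fov,
            slice_count=slice_count_insert,
            noise_model=model,
            seed=seed + 1,
            insert_diameter=insert_diameter,
            insert_contrast=insert_contrast,
            psf_sigma=psf_sigma,
            meta=dict(meta),
        )
    )
    return homog, insert
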