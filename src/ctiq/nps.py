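"""Noise power spectrum estimation and scalar noise metrics.

The 2-D NPS is estimated from square regions of interest (ROIs) placed in a
homogeneous image region. Each ROI is detrended with a 2nd-order polynomial
fit (removing slowly varying background/shading), and the normalised
periodograms of the residuals are averaged over all ROIs and slices:

    NPS2D(fx, fy) = (dx * dy / (Nx * Ny)) * mean_i |DFT2{ROI_i - FIT_i}|^2

with dx, dy the pixel size and Nx, Ny the ROI dimensions in pixels; this
normalisation (equivalently dx^2 dy^2 / (Lx Ly) with L the ROI side length
in mm) gives units of HU^2 mm^2 and makes the integral of the spectrum over
frequency equal the noise variance (Parseval), independent of ROI size.

The 1-D radial profile is the unweighted mean over annular frequency bins.
Scalar metrics: noise magnitude (square root of the area under the 2-D
spectrum, HU), the 1-D peak value (HU^2 mm^2), and the spectrum-weighted
mean frequency f_av (mm^-1) which characterises noise texture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .stack import ImageStack

__all__ = [
    "RoiLayout",
    "Nps2D",
    "Nps1D",
    "NoiseMetrics",
    "ring_layout",
    "detrend_roi",
    "compute_nps2d",
    "radial_average",
    "noise_metrics",
    "analyze_noise",
]

logger = logging.getLogger(__name__)


@dataclass
class RoiLayout:
    """Placement of square ROIs for NPS estimation.

    ``roi_origins`` are (row, col) positions of each ROI's top-left pixel.
    The protocol default is eight 104^2-pixel ROIs on a ring, evaluated over
    50 axial slices.
    """

    roi_size: int
    roi_origins: list[tuple[int, int]]
    slices_used: list[int] | None = None

    def __post_init__(self) -> None:
        if self.roi_size < 8:
            raise ValueError("roi_size must be >= 8 pixels")
        if len(self.roi_origins) < 1:
            raise ValueError("at least one ROI is required")

    @property
    def roi_count(self) -> int:
        return len(self.roi_origins)

    def validate_against(self, stack: ImageStack) -> None:
        n_rows, n_cols = stack.shape[1:]
        for r0, c0 in self.roi_origins:
            if r0 < 0 or c0 < 0 or r0 + self.roi_size > n_rows or c0 + self.roi_size > n_cols:
                raise ValueError(
                    f"ROI at origin ({r0}, {c0}) with size {self.roi_size} "
                    f"does not fit in a {n_rows}x{n_cols} image"
                )
        if self._any_overlap():
            logger.info("ROI layout contains overlapping ROIs")

    def _any_overlap(self) -> bool:
        s = self.roi_size
        origins = self.roi_origins
        for i in range(len(origins)):
            for j in range(i + 1, len(origins)):
                (r1, c1), (r2, c2) = origins[i], origins[j]
                if abs(r1 - r2) < s and abs(c1 - c2) < s:
                    return True
        return False


def ring_layout(
    stack_shape: tuple[int, int],
    roi_size: int = 104,
    roi_count: int = 8,
    ring_radius: int | None = None,
) -> RoiLayout:
    """Place ``roi_count`` ROIs with centres evenly spaced on a ring.

    The ring is centred on the image centre; its default radius is the
    largest that keeps every ROI fully inside the image with a small margin.
    """
    n_rows, n_cols = stack_shape
    half = roi_size / 2.0
    if ring_radius is None:
        ring_radius = int(min(n_rows, n_cols) / 2 - half - 2)
    if ring_radius < 0:
        raise ValueError("image too small for the requested ROI size")
    cr, cc = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    origins = []
    for k in range(roi_count):
        theta = 2.0 * math.pi * k / roi_count
        r0 = int(round(cr + ring_radius * math.sin(theta) - half))
        c0 = int(round(cc + ring_radius * math.cos(theta) - half))
        origins.append((r0, c0))
    return RoiLayout(roi_size=roi_size, roi_origins=origins)


@dataclass
class Nps2D:
    """2-D noise power spectrum on the DC-centred ROI frequency grid."""

    values: np.ndarray  # HU^2 mm^2
    freq_x: np.ndarray  # mm^-1, DC-centred
    freq_y: np.ndarray
    pixel_spacing: float
    roi_layout: RoiLayout | None = None
    meta: dict = field(default_factory=dict)

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_spacing)

    @property
    def grid_step(self) -> float:
        return float(self.freq_x[1] - self.freq_x[0])


@dataclass
class Nps1D:
    """Radial (annular-mean) profile of a 2-D NPS."""

    freq: np.ndarray  # mm^-1, strictly increasing
    values: np.ndarray  # HU^2 mm^2
    bin_width: float


@dataclass
class NoiseMetrics:
    """Scalar noise descriptors derived from the NPS."""

    noise_magnitude: float  # HU
    nps1d_peak: float  # HU^2 mm^2
    f_av: float | None  # mm^-1; None when the spectrum is identically zero


def _poly2_basis(n: int) -> np.ndarray:
    """6-term 2nd-order polynomial design matrix {1, x, y, x^2, xy, y^2} on an n x n grid."""
    c = (np.arange(n) - (n - 1) / 2.0) / max(n - 1, 1)
    x, y = np.meshgrid(c, c)
    cols = [np.ones_like(x), x, y, x**2, x * y, y**2]
    return np.stack([col.ravel() for col in cols], axis=1)


def detrend_roi(roi_pixels: np.ndarray) -> np.ndarray:
    """Subtract the least-squares 2nd-order polynomial surface from a square ROI."""
    roi = np.asarray(roi_pixels, dtype=float)
    if roi.ndim != 2 or roi.shape[0] != roi.shape[1]:
        raise ValueError("ROI must be a square 2-D array")
    if roi.shape[0] < 8:
        raise ValueError("ROI side must be >= 8 pixels")
    basis = _poly2_basis(roi.shape[0])
    coeffs, *_ = np.linalg.lstsq(basis, roi.ravel(), rcond=None)
    return roi - (basis @ coeffs).reshape(roi.shape)


def compute_nps2d(stack: ImageStack, layout: RoiLayout) -> Nps2D:
    """Average the normalised periodograms of all detrended ROIs over all slices."""
    layout.validate_against(stack)
    slices = layout.slices_used
    if slices is None:
        slices = list(range(stack.n_slices))
    if len(slices) == 0:
        raise ValueError("no slices selected")
    n = layout.roi_size
    dx = stack.pixel_spacing
    basis = _poly2_basis(n)
    # precompute the pseudo-inverse once: detrending is a fixed projection
    pinv = np.linalg.pinv(basis)

    accum = np.zeros((n, n))
    count = 0
    for s in slices:
        img = stack.voxels[s]
        for r0, c0 in layout.roi_origins:
            roi = img[r0 : r0 + n, c0 : c0 + n]
            resid = roi - (basis @ (pinv @ roi.ravel())).reshape(n, n)
            accum += np.abs(np.fft.fft2(resid)) ** 2
            count += 1
    # dx*dy / (Nx*Ny) normalisation -> HU^2 mm^2, ROI-size invariant
    values = np.fft.fftshift(accum) * (dx * dx) / (n * n) / count
    freq = np.fft.fftshift(np.fft.fftfreq(n, d=dx))
    return Nps2D(
        values=values,
        freq_x=freq.copy(),
        freq_y=freq.copy(),
        pixel_spacing=dx,
        roi_layout=layout,
        meta=dict(stack.meta),
    )


def radial_average(nps2d: Nps2D) -> Nps1D:
    """Reduce a 2-D NPS to its radial profile by unweighted annular means.

    Bins have the width of one frequency-grid step; each bin's centre is the
    mean radial frequency of its member cells. Bins whose centre lies beyond
    the Nyquist circle are discarded; empty bins are merged into their
    lower neighbour.
    """
    df = nps2d.grid_step
    fx, fy = np.meshgrid(nps2d.freq_x, nps2d.freq_y)
    fr = np.hypot(fx, fy).ravel()
    vals = nps2d.values.ravel()
    idx = np.floor(fr / df + 0.5).astype(int)  # bin 0 centred on DC
    n_bins = idx.max() + 1
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    fsums = np.bincount(idx, weights=fr, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)

    freq_out, val_out = [], []
    pend_sum = pend_fsum = pend_cnt = 0.0
    for b in range(n_bins):
        pend_sum += sums[b]
        pend_fsum += fsums[b]
        pend_cnt += counts[b]
        if counts[b] > 0:
            freq_out.append(pend_fsum / pend_cnt)
            val_out.append(pend_sum / pend_cnt)
            pend_sum = pend_fsum = pend_cnt = 0.0
    freq_arr = np.asarray(freq_out)
    val_arr = np.asarray(val_out)
    keep = freq_arr <= nps2d.nyquist + 1e-12
    return Nps1D(freq=freq_arr[keep], values=val_arr[keep], bin_width=df)


def noise_metrics(nps2d: Nps2D, nps1d: Nps1D | None = None) -> NoiseMetrics:
    """Noise magnitude, 1-D peak, and average spatial frequency f_av.

    noise_magnitude = sqrt(sum(NPS2D) * du * dv) — by Parseval this equals
    the standard deviation of the detrended noise. f_av is the NPS1D-weighted
    mean of the binned radial frequency.
    """
    if nps1d is None:
        nps1d = radial_average(nps2d)
    df = nps2d.grid_step
    area = float(nps2d.values.sum()) * df * df
    magnitude = math.sqrt(max(area, 0.0))
    total = float(nps1d.values.sum())
    if total <= 0:
        logger.warning("all-zero spectrum: f_av is undefined")
        return NoiseMetrics(noise_magnitude=magnitude, nps1d_peak=0.0, f_av=None)
    f_av = float(np.sum(nps1d.freq * nps1d.values) / total)
    return NoiseMetrics(
        noise_magnitude=magnitude,
        nps1d_peak=float(nps1d.values.max()),
        f_av=f_av,
    )


def analyze_noise(
    stack: ImageStack, layout: RoiLayout | None = None
) -> tuple[Nps2D, Nps1D, NoiseMetrics]:
    """Convenience wrapper: 2-D NPS, radial profile and scalar metrics in one call."""
    if layout is None:
        shape = stack.shape[1:]
        roi = 104 if min(shape) >= 160 else max(min(shape) // 4, 32)
        layout = ring_layout(shape, roi_size=roi)
    nps2d = compute_nps2d(stack, layout)
    nps1d = radial_average(nps2d)
    return nps2d, nps1d, noise_metrics(nps2d, nps1d)
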