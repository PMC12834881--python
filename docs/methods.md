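# Methods

This note documents the models, conventions and numerical choices behind
`ctiq`, and what the synthetic validation does and does not demonstrate
about real CT data.

## Synthetic phantom generator

The generator emulates axial acquisitions of an image-quality phantom:
a homogeneous section for noise analysis and a cylindrical-insert section
for edge analysis, at the protocol geometry of the emulated study
(320.3 mm field of view; 512² matrix → 0.6256 mm pixels, 1,024² matrix →
0.3128 mm pixels; 1 mm slices; dose levels 3.0, 5.9, 12.7 mGy).

**Correlated noise by spectral shaping.** Each slice is
`ifft2(sqrt(S) · fft2(w))` with `w` unit white Gaussian noise and `S` the
target discrete spectrum, scaled so the per-pixel variance equals the
requested magnitude² exactly in expectation (the DC cell is zeroed, so
slices are mean-free). The true NPS of the generated field is therefore
known in closed form — `pixel_spacing² · S` — and serves as the oracle for
the NPS estimator. Slices are statistically independent; axial analysis
treats them independently, and z-correlation is out of scope. Spectrum
shapes: white; a radial Gaussian lobe (`center`, `width`); and arbitrary
tabulated radial curves.

**Inserts.** The disk is rasterised by area-weighted supersampling
(8 × 8 sub-samples for rim pixels, exact 0/1 elsewhere) so the sub-pixel
edge position — the very thing the circular-edge technique measures — is
represented faithfully; it is then convolved with a sampled Gaussian PSF
and noise is added per slice. The measured transfer function is thus the
analytic Gaussian MTF times the (small) pixel-aperture term, which is the
physically correct sampled-system response.

**Dose and algorithm/level presets.** Noise magnitude scales as
1/√CTDIvol relative to a calibration defined at 12.7 mGy — the standard
quantum-noise scaling (the emulated study measures noise, it does not
model it, so no scaling is printed there). The built-in presets for a
normal-resolution (512²) and a super-resolution (1,024²) reconstruction
at three strength levels are *illustrative*: magnitudes at the reference
dose follow the pattern of the reference measurements; the noise texture
uses a ramp-Gaussian radial spectrum `f²·exp(−(f/b)²)` with `b` set from
the target mean frequency (f_av = 2b/√π); texture coarsens
(f_av ∝ dose^0.15) and the PSF widens (σ ∝ dose^−0.2) at lower dose,
mimicking the dose dependence a nonlinear reconstruction exhibits. The
normal-resolution preset keeps f_av flat across levels (as the reference
table shows at the highest dose), and the super-resolution f_av ladder is
0.40/0.32/0.28 mm⁻¹ — slightly tempered relative to the reference
pattern so that, under the simple ramp-Gaussian model, the low-frequency
noise density decreases monotonically with level, as the real
measurements imply. The presets make no claim about any commercial
algorithm.

## NPS estimation

Eq.-style estimator: each square ROI is detrended by a least-squares fit
over the six-term basis {1, x, y, x², xy, y²} and the periodograms of the
residuals are averaged over ROIs × slices, normalised by
`Δx·Δy / (N·N)`. This normalisation gives HU²·mm², makes the integral of
the spectrum equal the noise variance (verified against the sample
standard deviation of the detrended pixels to 1%), and renders the
estimate ROI-size invariant. The default layout is eight 104²-pixel ROIs
with centres on a ring around the image centre (the ring radius defaults
to the largest that keeps ROIs inside the image; exact positions in the
reference figure are not published, and positions are configurable).
Overlapping ROIs are permitted and logged. No window is applied beyond
detrending.

The radial profile is the *unweighted* annular mean in bins one grid step
wide (no 2πf weighting), bin centres at the mean radial frequency of the
member cells; empty bins merge into their upper neighbour and bins beyond
the Nyquist circle are dropped. f_av is the value-weighted mean frequency
of that binned curve — the convention of the noise-texture literature.

*Known limitation:* a detrended periodogram cannot estimate the DC cell
(detrending removes it by construction), so spectrum-fidelity comparisons
exclude the DC bin. The taper-free estimator also leaks power across
~1/L (L = ROI side length in mm): narrow spectral lobes (width
≲ 0.05 mm⁻¹) are broadened by a few percent, which is irrelevant for the
broad lobes real CT noise exhibits but visible on contrived narrowband
inputs.

## TTF by the circular edge

The insert centre and radius are refined on the slice-averaged image:
half-contrast thresholding, intensity-weighted centroid, radius from the
enclosed area (recovers sub-pixel offsets to < 0.1 px on synthetic
truth). All annulus pixels within ±6 mm (default) of the rim are pooled
over slices as (radial distance − radius, value) pairs and binned at 0.1
pixel; empty bins are filled by linear interpolation. Plateau means come
from the innermost and outermost 30% of the annulus span. The LSF is the
central-difference derivative of the ESF; a Hann window centred on the
LSF peak (width = the full binned support) suppresses noise-driven
leakage before the FFT. The TTF is the normalised modulus; f50 is found
by linear interpolation at the first downward crossing of 0.5. No
finite-difference (sinc) compensation is applied; at 0.1-pixel binning
the effect is ≪ 1% below f50. ESF samples are pooled across slices
rather than averaging per-slice TTFs: pooling is the standard noise
-suppression practice for the circular edge, and per-slice averaging
would bias the estimate at high noise through the per-slice modulus.

Validated recoveries: f50 within 5% of the analytic Gaussian value for
PSF σ ∈ {0.3, 0.5, 0.8} mm at up to 15 HU noise with 100-slice pooling
(biases: aperture/curvature ≈ −3.5% at σ = 0.3, window truncation
≈ +3.4% at σ = 0.8, ≈ +0.2% at σ = 0.5); strict monotone decrease of f50
with σ; contrast invariance within 2% between 85 and 350 HU inserts (the
simulator is linear — any contrast dependence measured on real data is a
property of the reconstruction, which is what the task-based method is
for).

## NPWE detectability

The lesion is circular with a Gaussian contrast profile; the nominal
diameter maps to the FWHM (σ_lesion = diameter/2.35482 — the conventional
reading for a Gaussian designer profile; the mapping is isolated in one
constant). W is the analytic continuous Fourier transform of the bump —
not a raster FFT — eliminating discretisation bias;
W(0,0) = C·2πσ_lesion². The eye filter is E(ρ) = ρ^1.3·exp(−cρ²) with
c = γ/(2ρ_peak²) so E peaks at 4 cycles/degree, normalised to max 1;
image frequency f maps to ρ = (f/zoom)·distance·π/180 with
zoom = display/fov (180 mm display, 500 mm distance, 320.3 mm fov ⇒
zoom = 0.562). Parameters are configurable since the underlying visual
-model reference is not reprinted in the source study. `eye_filter="none"`
gives the ideal-observer fallback E ≡ 1.

Both integrals are evaluated by the trapezoid rule on a Cartesian grid
spanning ±Nyquist of the NPS input with 512² nodes (doubling changes d′
by < 0.2%; the white-noise/ideal-TTF closed form
d′ = √(C²πσ²/N₀) is reproduced to machine precision). The NPS enters as
its radial profile interpolated onto the grid — isotropy is assumed, as
for the generator's radially symmetric spectra; negative interpolated
values are clipped to zero. Each reconstruction is integrated to its own
Nyquist (matrix-dependent), and each task uses the TTF of its matching
insert (350 HU task ↔ high-contrast insert, 85 HU task ↔ low-contrast
insert).

## Comparison statistics

Percent differences are 100·(b − a)/a with the baseline named second in
"B versus A" contrasts; summaries are the mean and *sample* SD (n − 1)
across the matched conditions. The n−1 convention is locked by the only
statistic whose SD regenerates exactly from the reference table (the 1-D
NPS-peak contrast: 7.3 with n−1, 6.9 with n). Six quoted statistics
regenerate from the printed cells to one decimal; the super-resolution
level-1→2 contrast regenerates as −44.5 versus the printed −44.4 ± 0.8
(rounding-limited — the unrounded source values are unavailable), and
f_av/f50/d′ contrasts are similarly rounding-limited and are reported but
not asserted. No inferential statistics are produced: there is one
measurement per condition.

## Problem sizes

Estimator-oracle validation runs at the full protocol averaging scale
(8 × 104² ROIs over 50 slices on 512² noise; 100-slice edge pooling at
the 1,024-matrix pixel size on a 256² window around the insert). The
full-study sweep (2 algorithms × 3 levels × 3 doses) runs on
quarter-scale matrices at the protocol pixel spacings with 40
homogeneous and 30 insert slices per condition — enough averaging to
resolve the smallest preset step in d′ (≈ 3.5% between adjacent
normal-resolution levels) reliably, in the same spirit as the protocol's
own slice pooling.

## What passing tests show — and don't

The synthetic stacks are stationary, Gaussian, slice-independent and
generated by a *linear* system. Passing oracles therefore validates the
estimators (normalisation, geometry, quadrature, conventions), not the
behaviour of any nonlinear reconstruction: contrast-dependent resolution,
non-stationary noise, z-correlation and texture nonlinearity in real DLR
images are exactly the phenomena the estimators exist to measure and are
not emulated. Absolute d′ values from reduced-scale runs depend on the
simulated field of view and are meaningful only relative to one another.
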