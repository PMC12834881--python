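# ctiq — task-based CT image-quality assessment

`ctiq` implements the task-based image-quality chain used to characterise
CT reconstruction algorithms on standard image-quality phantoms: the
**noise power spectrum** (NPS) estimated from detrended regions of
interest in a homogeneous section, the **task-based transfer function**
(TTF) measured on a cylindrical insert by the circular-edge technique, and
the **NPWE model-observer detectability index** d′ that combines the two
with a lesion model and the human contrast-sensitivity function. It is
aimed at medical physicists comparing reconstruction algorithms, strength
levels and dose levels — for instance normal-resolution (512²) versus
super-resolution (1,024²) deep-learning reconstructions of an abdominal
protocol — without access to the proprietary reconstructions themselves:
a synthetic phantom generator with *analytically known* noise spectra and
edge blur provides exact oracles for every estimator.

## The metrics

With pixel size Δx, Δy and N×N-pixel ROIs, the 2-D NPS is the averaged
periodogram of the 2nd-order-polynomial-detrended ROIs,

    NPS₂D(fx, fy) = (Δx·Δy / (N·N)) · ⟨ |DFT₂{ROIᵢ − FITᵢ}|² ⟩ᵢ  [HU²·mm²],

whose integral equals the noise variance (Parseval); its radial profile
yields the noise magnitude (HU), the 1-D peak (HU²·mm²) and the
spectrum-weighted mean frequency f_av (mm⁻¹, noise texture). The TTF is
the modulus of the Fourier transform of the angle-averaged line spread
function around the insert rim, normalised to 1 at DC; f50 (mm⁻¹) is
where it falls to 0.5. The NPWE detectability index is

    d′² = [∬ |W|² TTF² E² du dv]² / ∬ |W|² TTF² NPS E⁴ du dv,

with W the Fourier magnitude of the lesion-present minus lesion-absent
difference (a circular Gaussian bump, FWHM = nominal diameter, evaluated
analytically) and E the Eckstein-style eye filter ρ^1.3·exp(−cρ²) in
cycles/degree, peaking at 4 cyc/deg, mapped to image frequencies through
the display zoom and viewing distance.

## Worked example

`examples/02_task_transfer_function.py` builds a 25-mm insert blurred by a
0.5-mm Gaussian PSF, pools the circular-edge profile over 100 noisy
slices (σ = 10 HU) and prints:

```
refined centre  : (+0.000, +0.000) mm (true: 0, 0)
refined radius  : 12.509 mm (true: 12.5)
edge contrast   : 349.9 HU (true: 350)
measured f50    : 0.3755 mm^-1
analytic  f50   : 0.3748 mm^-1 for a 0.5 mm Gaussian PSF
```

The sub-pixel edge geometry is recovered to ~0.01 mm and the measured f50
agrees with the analytic Gaussian-MTF value to 0.2%. The other examples
cover NPS estimation (`01`), detectability (`03`), a full reduced-scale
study sweeping 2 algorithms × 3 levels × 3 doses (`04`), and the
regeneration of the reference study's summary statistics from its printed
tables (`05`), e.g. the 1-D NPS peak contrast between the two
reconstructions, −59.8 ± 7.3% across all nine dose/level pairs.

A thin CLI mirrors the stages:

```sh
ctiq simulate --seed 1 --matrix-size 512 --fov 320.3 --slice-count 50 --out homog
ctiq nps homog.json --roi-size 104 --roi-count 8 --out metrics.json
ctiq run --seed 42 --scale 0.25 --out study/
```

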