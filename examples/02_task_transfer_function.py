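"""Measure spatial resolution with the circular-edge TTF.

Builds a 25-mm cylindrical insert blurred by a 0.5-mm Gaussian point
spread function, pools the edge profile over 100 noisy slices, and
compares the measured f50 with the analytic value for a Gaussian MTF.
"""

import math

import ctiq

matrix = 256
fov = matrix * 320.3 / 1024  # pixel size of the 1024-matrix protocol

spec = ctiq.PhantomSpec(
    matrix_size=matrix, fov=fov, slice_count=100,
    noise_model=ctiq.NoiseModel(magnitude=10.0), seed=2,
    insert_diameter=25.0, insert_contrast=350.0, psf_sigma=0.5,
)
stack = ctiq.make_insert_stack(spec)

center, radius = ctiq.locate_edge(stack)
profile = ctiq.build_esf(stack, center, radius)
result = ctiq.compute_ttf(profile)

analytic = math.sqrt(math.log(2) / (2 * math.pi**2 * 0.5**2))
print(f"refined centre  : ({center[0]:+.3f}, {center[1]:+.3f}) mm (true: 0, 0)")
print(f"refined radius  : {radius:.3f} mm (true: 12.5)")
print(f"edge contrast   : {profile.contrast:.1f} HU (true: 350)")
print(f"measured f50    : {result.f50:.4f} mm^-1")
print(f"analytic  f50   : {analytic:.4f} mm^-1 for a 0.5 mm Gaussian PSF")
print()
print("f50 is the frequency where the transfer function drops to 0.5;")
print("higher f50 means sharper edges between tissues.")
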