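"""Fit membrane curvature on a synthetic bending phosphorus lattice.

Generates a membrane that bends to R = 500 Å (κ = 0.020 nm⁻¹) under
0.5 Å positional noise, fits a circle per frame in the 160 × 10 Å²
patch, and averages the final third of frames — the same windowed
statistic used for a production trajectory.
"""

import numpy as np

import barbend as bb

spec = bb.MembraneSpec(radius_series=[500.0] * 300, noise_sd=0.5, seed=0)
trajectory, truth = bb.generate_membrane_trajectory(spec)

series = bb.curvature_series(trajectory,
                             region=bb.FitRegion(anchor="absolute"),
                             window_fraction=1 / 3)

print(f"true curvature        : {truth.kappa_nm[0]:.4f} nm^-1")
print(f"window mean curvature : {series.window_mean:.4f} nm^-1")
print(f"window sd             : {series.window_sd:.4f} nm^-1")
print(f"fitting radius        : {1.0 / series.window_mean:.1f} nm")
# The window mean recovers the planted 0.0200 nm^-1 within a few
# percent; the sd reflects the per-frame fit noise, the analog of the
# error bands on a curvature-vs-time plot.
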