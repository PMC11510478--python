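"""Arm/core segmentation and the angle–span correlation of a swinging dimer.

Builds a pseudo-dimer whose arm segments (VAL114–SER157) swing about the
Helix-2 kink with a planted Pearson correlation of 0.65 between the
arm–arm angle α and the dimer span d, then recovers α, β, γ, d from the
coordinates alone and re-estimates the correlations.
"""

import barbend as bb

trajectory, truth = bb.generate_dimer_trajectory(
    bb.DimerSpec(seed=1),
    bb.MotionSpec(n_frames=3000, correlation_alpha_d=0.65, seed=11))

series = bb.angle_span_series(trajectory)
table = bb.correlation_summary(series,
                               pairs=[("alpha", "d"), ("beta", "d"),
                                      ("gamma", "d"), ("alpha", "beta")])
print(table.to_string(index=False))
print(f"\nmean alpha {series.alpha_deg.mean():.1f} deg, "
      f"mean span {series.d_A.mean():.1f} A")
# alpha-d comes back near the planted 0.65; beta-d stays near zero
# because the core segments move independently of the span — the
# signature of arms, not whole monomers, driving span fluctuations.
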