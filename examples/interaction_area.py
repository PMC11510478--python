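"""Solvent-accessible surface area and the monomer–monomer buried area.

The per-partner interaction area of a complex is
(SASA_A + SASA_B − SASA_AB)/2.  On a two-sphere fixture the value has a
spherical-cap closed form, which the point-sampled estimate reproduces
within ~1%.
"""

import numpy as np

import barbend as bb

traj, radii = bb.generate_sphere_fixture(1.9, 1.9, 3.0)
params = bb.SASAParams(radii_table=radii)
res = bb.interaction_area(traj.topology, traj.frames[0], [0], [1], params)

r_eff = 1.9 + params.probe_radius
analytic = 2 * np.pi * r_eff * (r_eff - 3.0 / 2.0)
print(f"SASA A        : {res.sasa_A:8.2f} A^2")
print(f"SASA B        : {res.sasa_B:8.2f} A^2")
print(f"SASA complex  : {res.sasa_AB:8.2f} A^2")
print(f"buried area   : {res.area:8.2f} A^2  (cap closed form {analytic:.2f})")
# For a real dimer the same triple of SASA evaluations quantifies how
# tightly the two monomers pack; a stable value over time means the
# opening angle between monomers barely moves.
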