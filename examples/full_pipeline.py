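"""Run the complete analysis pipeline on a synthetic membrane + dimer bundle.

Writes a coord_table CSV bundle, then runs align → curvature → geometry
→ interactions → displacement from one config and prints the rendered
report.  Outputs land in ./pipeline_out (CSVs per stage + report.json).
"""

import tempfile
from pathlib import Path

import barbend as bb

n = 60
membrane, mem_truth = bb.generate_membrane_trajectory(
    bb.MembraneSpec(radius_series=[500.0] * n, noise_sd=0.3, seed=4))
dimer, _ = bb.generate_dimer_trajectory(
    bb.DimerSpec(seed=5),
    bb.MotionSpec(n_frames=n, correlation_alpha_d=0.65, seed=6))
bundle = bb.place_dimer_on_membrane(membrane, dimer)

workdir = Path(tempfile.mkdtemp())
paths = bb.write_bundle(bundle, bb.GroundTruth(kappa_nm=mem_truth.kappa_nm),
                        workdir)

config = bb.RunConfig(coords=str(paths["coords"]),
                      topology=str(paths["topology"]),
                      format="coord_table",
                      output_dir="pipeline_out")
report = bb.run_pipeline(config)
print(bb.report_render(report))
# The curvature section recovers the planted 0.0200 nm^-1; the geometry
# section's alpha-d correlation approaches 0.65 as frames accumulate;
# displacement stays flat because this bundle holds the bend radius fixed.
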