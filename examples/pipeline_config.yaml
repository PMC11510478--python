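# Example pipeline configuration (flat RunConfig keys) for a real
# BAR-dimer + membrane trajectory:
#   barbend run --config examples/pipeline_config.yaml \
#               --coords traj_coords.csv --topology structure.pdb
# The residue groups below name residues of the real construct; for the
# synthetic pseudo-dimer bundle (all-ALA chains) leave `groups` empty.
coords: null            # coord_table CSV (override on the command line)
topology: null          # topology PDB
format: coord_table
output_dir: barbend_out

membrane_atom_name: P   # lipid reference atoms
dimer_atom_name: CA
dimer_chains: [A, B]

region_length_x: 160.0  # fit strip beneath the dimer, Å
region_width_y: 10.0
region_anchor: dimer_footprint
window_fraction: 0.3333333333333333

core_range: [92, 114]   # Helix 2 split at the VAL114 kink
arm_range: [114, 157]
span_anchor_residue: 157
center_residue: 69      # concave-surface center (GLY69, both chains)

hbond_da_cutoff: 3.5
hbond_angle_cutoff: 30.0
sasa_probe_radius: 1.4
sasa_n_points: 960

# Charged-residue clusters on the concave face. Only the two clusters
# named in the literature for this construct are listed; add further
# clusters for your own system as chain:resnum:resname strings.
groups:
  group1: ["A:19:ARG", "A:23:LYS"]
  group2: ["A:47:LYS", "A:48:ARG", "A:132:LYS"]

pooling: pooled
seed: 0
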