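# Methods

This note records the models, conventions, parameter defaults and known
limitations of the package, in the order an analysis runs.

## Units and addressing

Internal lengths are ångströms everywhere; GRO input (nm) is scaled by
10 on read. Curvature is converted at the reporting layer only:
κ [nm⁻¹] = 10 × κ [Å⁻¹] = 10 / R [Å]. Times are picoseconds. Chains
are addressed by single letters, residues by 1-based PDB numbers, and
residue ranges are inclusive at both ends ("GLY69A" = chain A, residue
69).

## Frame alignment

All membrane and displacement analyses assume the analysis convention:
membrane plane normal along +z (oriented toward the protein), dimer
long axis along x, membrane centroid at the origin. `align_frames`
establishes it per frame with a rigid transform: the plane is the
best-fit (least-squares) plane of the membrane phosphorus atoms, the x
direction is the principal axis of the dimer Cα cloud projected into
that plane. Because a principal axis has no intrinsic sign, the sign is
fixed deterministically: the dimer atom farthest from the dimer
centroid gets a positive x projection, ties broken by lowest topology
index. Collinear membrane points (plane undefined) raise an alignment
error. Internal distances are preserved to floating-point precision.

## Membrane curvature

Phosphorus atoms inside a rectangle (default 160 × 10 Å², long side
along x) centered on the dimer footprint centroid — or on an absolute
origin for the no-protein control — are projected to the x–z plane; the
10 Å strip is thin enough that the y spread is treated as noise and
collapsed by projection rather than binned.

The per-frame estimator is a least-squares circle. The algebraic Kåsa
solution (ordinary least squares on the linearized circle equation in
centered coordinates) is closed-form and exact on noiseless circular
data, but for shallow arcs under positional noise it is biased toward
smaller radii: at R = 1000 Å, 1 Å noise and the default patch it
overestimates curvature by roughly a factor of two. `curvature_series`
therefore refines the Kåsa seed with an orthogonal-residual
Levenberg–Marquardt fit by default (`refine=True`), which brings the
recovery error across R ∈ {250, 500, 1000} Å and noise ∈ {0, 0.5, 1} Å
below ~4%. `fit_circle` itself defaults to the pure algebraic solution
so the primitive remains directly comparable to its circumcircle
oracle.

Conventions: input collinear to better than 1e-7 Å rms maps to the
flat-membrane result (R = ∞, κ = 0, sign +1) rather than an error, so
flat controls run cleanly. The sign is +1 when the fitted circle
center lies below the mean patch height — the membrane bulging toward
the protein side — and −1 otherwise; κ itself is reported unsigned.
Frames with fewer than 3 patch atoms are flagged infeasible, excluded
from window statistics, and counted. The summary window is the
trailing fraction of frames (default one third, mirroring the practice
of averaging the final segment of a production run, e.g. the last 100
of 300 ns); window mean and sd are over feasible frames only.

R = 1/κ by definition throughout the package.

## Dimer geometry

Segment axes for arm, core and whole-Helix-2 ranges are principal
components of the segment's Cα coordinates, oriented N→C. For the
default segment lengths (≥ 23 residues) the principal axis tracks the
helix axis to well under 1°. The canonical ranges are core
ARG92–VAL114 and arm VAL114–SER157; the two ranges deliberately share
the kink residue. γ uses the union range (ARG92–SER157). The span d is
the distance between the SER157 Cα atoms of the two chains. Angles are
folded to [0, 180]°.

Kink detection slides two adjacent non-overlapping windows (default 6
Cα) along the helix and measures the angle between their local axes at
each junction. The local axis is *not* a principal component: at
window length 6 the 2.3 Å helical radius rivals the 7.5 Å axial extent
and raw PCA misestimates the axis by tens of degrees. Instead each
window's axis is the average of cross products of successive Cα
bisectors (A_i = (p_{i−1} − p_i) + (p_{i+1} − p_i)), which is exact on
ideal helical geometry for any window of ≥ 4 atoms. Calls are made per
contiguous above-threshold run of junctions (default threshold 20°);
the reported center is the median junction of the near-maximal plateau
(within 1° of the run maximum), which is robust to the slight
overshoot of windows that straddle the hinge, and the reported angle
is the run maximum. On planted kinks this recovers the hinge residue
within ±1 and the bend angle within ±1°.

Pearson correlations are sample product-moment coefficients (SciPy); a
constant input series raises a dedicated error and is reported as
missing, never as 0. `correlation_summary` pools frames across
trajectories by default ("pooled"); a per-trajectory mode averages the
per-run coefficients and both record the mode in the output.

RMSD uses Kabsch superposition (via SciPy's rotation alignment) per
frame against the first frame or an external reference. RMSF
superposes every frame onto the running mean structure, re-estimating
the mean twice (two-pass), then reports per-atom RMS deviations
aggregated per residue. For isotropic per-axis jitter σ the expected
RMSF is σ√3; superposition leaks a small fraction of a single
residue's fluctuation into the global fit, which decays as 1/N with
selection size (about 2% at 100 atoms).

## Interactions

SASA is Shrake–Rupley: each atom's Bondi van der Waals sphere is
inflated by the probe radius (default 1.4 Å, water) and sampled with a
deterministic Fibonacci (golden-spiral) point set, 960 points per atom
by default; a point is accessible when outside every other inflated
sphere of the same body. 960 points hold the single-sphere closed form
to well under 1% and the two-sphere spherical-cap closed form to ~1%;
rigid-motion variation stays below 0.5%. Both parameters and the radii
table are configurable. The interaction area of a complex is
(SASA_A + SASA_B − SASA_AB)/2 from three SASA evaluations on the same
frame; it is exactly symmetric in A and B, and small negative values
from point-sampling noise are clamped to zero and flagged.

Hydrogen bonds are geometric: donor–acceptor distance ≤ 3.5 Å and
hydrogen–donor–acceptor angle ≤ 30°, both inclusive — the convention of
standard MD analysis tooling, exposed in `HBondCriteria`. Hydrogens
are attached to donors geometrically (≤ 1.25 Å); topologies without
hydrogens (coarse Cα fixtures) fall back to a distance-only criterion
that labels itself in the output. Grouped series count bonds per
charged-residue cluster by donor residue and per lipid residue name by
acceptor. Only the two clusters named in the literature for this
construct (group 1: ARG19, LYS23; group 2: LYS47, ARG48, LYS132) are
shipped as an example configuration; further clusters are user
configuration, not guesses.

## Synthetic data

The generators define the study conditions; they are pure functions of
spec + seed.

**Membrane.** An nx × ny lattice (default 41 × 4 at 8 Å spacing — a
320 Å strip comfortably containing the 160 Å fit window, 21 × 2 atoms
inside it) of pseudo-phosphorus atoms. Frame t maps the flat lattice
coordinate s (an arc length) onto a cylinder of radius R(t) bent along
x: x = R sin(s/R), z = R(cos(s/R) − cos(S/R)) with S the half extent —
an upward dome with apex over the center, bulging toward the protein
side, its apex height equal to the sagitta of the bent patch. Arc-length
preservation makes the patch contract horizontally as it bends, which
is what the displacement analysis measures. Isotropic Gaussian noise
(default 0; typical tests use 0.5–1 Å, the scale of headgroup
roughness) is added after bending. R below the half extent would wrap
the patch and is rejected. True curvature is 10/R nm⁻¹, 0 for flat.

**Dimer.** Chain A is an ideal Cα helix (rise 1.5 Å/residue, twist
100°/residue, radius 2.3 Å) for residues 19–239, with a static kink
(default 40°, matching the Helix-2 kink magnitude of the construct) at
residue 114: all downstream residues are rigidly rotated about the lab
y axis through the kink Cα. Chain B is the mirror image through x = 0.
It is a Cα-only caricature — no three-helix bundle packing — which is
sufficient because every dimer metric uses only Cα positions, and it
keeps the ground truth closed-form. Per frame the arm pivots further
about the same hinge by a pitch angle θ(t); with both arms in the x–z
plane, α(t) = 180° − 2(κ₀ + θ(t)) exactly under a shared pitch, and the
span shrinks as the arms tip up. Ground-truth α*, β* are angles between
the explicitly composed rotation-matrix axes, γ* between the chord
vectors P92→P157, and d* is the distance between the built SER157
positions — closed-form geometry, never the estimators under test.

Arm motion is a stationary Ornstein–Uhlenbeck process by default
(exact AR(1) discretization, relaxation time 10 frames, stationary sd
= amplitude, default 5°), reproducing an oscillating swing without
committing to any particular dynamics; a sinusoid is available. When a
target Pearson(α, d) = ρ is requested the coupling is built
constructively from two channels: a shared arm pitch, which moves α
and d together with sensitivity dd/dθ = 2 L_arm sin κ₀, and an
independent symmetric rigid x translation of the chains (an interface
"breathing" mode), which moves d only and leaves every angle exactly
unchanged. The small-angle variance mixing ratio sets the breathing
amplitude; at 3000 frames the sample correlation lands within ±0.05 of
the target. Core segments receive independent small pitch jitter
(default sd 2°) about the same hinge so that β is uncorrelated with d.
Arm rotations that bring arm atoms within 1 Å of the rest of the chain
are rejected as self-intersecting. A deterministic
`arm_angle_series` overrides the stochastic driver for
parameter-recovery tests.

**Interaction fixtures.** The hydrogen-bond fixture plants near-linear
donor–H–acceptor triples at D···A = 2.8 Å (bonded) and 5.0 Å
(non-bonded) with seeded random orientations, 20 Å apart. The sphere
fixture returns two single-atom bodies with caller-chosen radii plus
the radii table to feed `SASAParams`.

What the generators do *not* emulate — and hence what passing tests do
not show about real data: lipid packing and headgroup chemistry,
thermal undulations beyond white positional noise, periodic-boundary
effects, secondary-structure changes, force-field energetics, explicit
solvent. The tests demonstrate that the estimators recover known
geometric signals at realistic noise scales, not that a particular
biological system behaves this way.

## Pipeline

`run_pipeline` validates the whole configuration first (all selection
and residue references, errors aggregated), then runs align →
curvature → geometry → interactions → displacement with stage
isolation: a failed stage is recorded and independent stages still run
(geometry needs no membrane, so it completes on a lipid-free
trajectory). Outputs are per-stage CSVs plus `report.json` /
`report.md`; the config echo in the report is sufficient to re-run
identically, and identical config + input + seed give byte-identical
CSVs. The monomer–monomer interaction area is evaluated on a
deterministic subsample of frames (default 5, evenly spaced) because
SASA is the one frame-cost-heavy quantity and its drift is slow.

## Problem sizes

Default test and acceptance sizes: 500-frame membranes for curvature
recovery, 3000-frame dimer runs for correlation recovery, 2000 frames
for the RMSF closed form, 40–60 frames for end-to-end pipeline checks.
These sizes put sampling error comfortably inside the stated
tolerances (e.g. the correlation estimate has an effective sample size
of ~150 after OU autocorrelation, s.e. ≈ 0.05 against a ±0.10 check)
while keeping the full suite under half a minute.

## Known limitations

* The membrane fit is a single 2-D circle per frame: no 2-D
  mean/Gaussian curvature fields, no leaflet resolution, no
  periodic-boundary unwrapping (trajectories are assumed whole).
* Kink calling reports one call per contiguous bend region; two kinks
  closer than about one window length merge.
* Hydrogen-bond detection is purely geometric; no energetic or
  electrostatic scoring, and donor/acceptor typing is by element (N/O)
  rather than chemistry-aware.
* Secondary-structure assignment and per-residue pairwise force
  decomposition are out of scope; established tools exist for both.
* Binary trajectory formats (XTC/DCD) are not parsed natively; the
  canonical interchange format is the plain-text coord_table CSV.
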