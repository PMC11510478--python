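# barbend

Trajectory geometry for BAR-domain membrane bending.

BAR domains are crescent-shaped dimeric protein modules that bind lipid
bilayers through a positively charged concave face and bend them into
curved structures. `barbend` implements the coordinate-level analyses
used to dissect that mechanism from molecular-dynamics trajectories of
a BAR dimer on a lipid patch:

* **Membrane curvature** — least-squares circle fitting (algebraic Kåsa
  solution, geometric orthogonal-residual refinement) of the lipid
  phosphorus atoms inside a 160 × 10 Å² strip beneath the dimer, with
  κ [nm⁻¹] = 10 / R [Å] and trailing-window averaging (default: final
  third of frames).
* **Arm/core segmentation** — Helix 2 of each monomer is split at the
  kink residue (VAL114) into a core segment (ARG92–VAL114) and an arm
  segment (VAL114–SER157); per frame the package computes the
  arm–arm angle α, core–core angle β, whole-Helix-2 angle γ, and the
  dimer span d (SER157 Cα to SER157 Cα), plus their Pearson
  correlations.
* **Helix kink detection** — paired sliding windows of Cα atoms with a
  bisector-cross local-axis estimate; bends above a threshold (default
  20°) are called at local maxima.
* **Interaction area** — Shrake–Rupley solvent-accessible surface area
  and the per-partner buried area
  S = (SASA_A + SASA_B − SASA_AB) / 2.
* **Hydrogen bonds** — geometric detection (D···A ≤ 3.5 Å,
  H–D–A ≤ 30°, both inclusive), grouped by charged-residue cluster and
  by lipid headgroup type.
* **Centripetal lipid displacement** — horizontal (in-plane) distance
  of tracked phosphorus atoms to the concave-surface center (mean
  GLY69 Cα position of the two chains).
* **RMSD / RMSF** — optimal-superposition deviation series and
  per-residue fluctuations about the iterated mean structure.

Because production MD trajectories of this system are large and rarely
shared, the package ships a first-class synthetic-data module: a
quasi-planar phosphorus lattice that bends toward a prescribed,
time-varying cylindrical radius, and a two-chain pseudo-dimer of kinked
helical Cα traces whose arms swing about the kink with a prescribed
amplitude and a by-construction correlation between α and d. Every
generator returns closed-form ground truth for the downstream
estimators, so all analyses are tested end to end against known
answers.

## Worked example

Fit membrane curvature on a synthetic bending lattice
(`examples/membrane_curvature.py`):

```python
import barbend as bb

spec = bb.MembraneSpec(radius_series=[500.0] * 300, noise_sd=0.5, seed=0)
trajectory, truth = bb.generate_membrane_trajectory(spec)
series = bb.curvature_series(trajectory,
                             region=bb.FitRegion(anchor="absolute"),
                             window_fraction=1 / 3)
```

prints

```
true curvature        : 0.0200 nm^-1
window mean curvature : 0.0201 nm^-1
window sd             : 0.0008 nm^-1
fitting radius        : 49.7 nm
```

The membrane was generated bending to R = 500 Å, i.e. a true curvature
of 0.0200 nm⁻¹; the windowed circle-fit estimate recovers it to within
half a percent under 0.5 Å positional noise, and the window standard
deviation quantifies the per-frame fit scatter (the error band one
would draw on a curvature-vs-time plot).

The other scripts in `examples/` demonstrate one capability each:
kink detection (`kink_detection.py`), the angle–span correlation of a
swinging dimer (`arm_swing_correlation.py`), SASA and buried area
against the spherical-cap closed form (`interaction_area.py`),
cluster-grouped hydrogen-bond counting (`hydrogen_bonds.py`), and the
full pipeline on a combined membrane + dimer bundle
(`full_pipeline.py`).

## Command line

A thin CLI wraps the library for shell use:

```bash
barbend simulate --out bundle --n-frames 300 --radius 500 --seed 1
barbend run --coords bundle/synthetic_coords.csv \
            --topology bundle/synthetic_topology.pdb --out results
barbend report results/report.json
```

Subcommands `curvature`, `geometry`, `sasa`, `hbonds` and
`displacement` run single stages; every flat key of the YAML config
(`--config`) can be overridden by a flag. Results are written as
per-frame CSVs plus a machine-readable `report.json`; log lines go to
stderr; the exit code is 0 only if all requested stages succeed.

## Layout

```
src/barbend/      library (trajectory I/O, synthetic data, membrane and
                  dimer geometry, interactions, pipeline, CLI)
examples/         one narrative script per capability
tests/            pytest suite incl. end-to-end acceptance checks
scripts/          acceptance.py
docs/methods.md   model assumptions, parameter defaults, limitations
```
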