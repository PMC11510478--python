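"""Synthetic coordinate trajectories with closed-form ground truth.

Two families of fixtures are generated:

* a quasi-planar lattice of pseudo-phosphorus atoms that bends toward a
  prescribed, possibly time-varying cylindrical radius (the membrane a
  BAR dimer would curve), and
* a two-chain pseudo-dimer of kinked helical Cα traces whose arm
  segments swing about the kink with prescribed amplitude and a
  by-construction correlation between the arm angle α and the dimer
  span d.

Every generator is a pure function of its spec and seed.  Ground-truth
quantities (κ*, α*, β*, γ*, d*) are computed from the same explicit
rotation matrices used to build the coordinates — closed-form geometry,
never the estimators under test.

Geometry of the pseudo-dimer
----------------------------
Chain A is an ideal Cα helix (rise 1.5 Å/residue, twist 100°/residue,
radius 2.3 Å) laid along +x, with a static kink of ``kink_angle_deg``
at the kink residue: all downstream residues are rigidly rotated about
the lab y-axis through the kink Cα, tipping the arm upward (+z).  Chain
B is the mirror image through the x = 0 plane.  Per frame, the arm is
further rotated about the same hinge by the pitch angle θ(t); because
both arms live in the x–z plane, the arm–arm angle obeys exactly

    α(t) = 180° − 2·(kink_angle + θ(t))        (shared pitch)

while the span d(t) shrinks as the arms tip up.  When a target
Pearson(α, d) is requested, d receives additional variance through a
symmetric rigid x-translation of the two chains (an interface
"breathing" mode) which leaves every angle unchanged; the small-angle
mixing ratio ρ = σ_d,pitch / √(σ_d,pitch² + σ_d,breathe²) sets the
translation amplitude.  Core segments get independent pitch jitter
about the same hinge so that β is uncorrelated with d.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SpecError
from .trajectory import Atom, Frame, Trajectory, write_coord_table

__all__ = [
    "MembraneSpec",
    "DimerSpec",
    "MotionSpec",
    "GroundTruth",
    "generate_membrane_trajectory",
    "generate_dimer_trajectory",
    "generate_kinked_helix",
    "generate_hbond_fixture",
    "generate_sphere_fixture",
    "place_dimer_on_membrane",
    "write_bundle",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class MembraneSpec:
    """Bending phosphorus-lattice membrane.

    ``radius_series`` holds the target cylindrical bend radius R(t) in Å
    per frame (``np.inf`` = flat).  The lattice is arc-length preserving:
    the flat x-coordinate of an atom becomes its arc position on the
    bent cylinder, so bending contracts the patch horizontally, exactly
    as a continuous membrane squeezed toward the center would.
    """

    nx: int = 41
    ny: int = 4
    spacing: float = 8.0            # Å
    radius_series: Sequence[float] = (np.inf,)
    noise_sd: float = 0.0           # Å, isotropic Gaussian
    seed: int = 0
    dt: float = 100.0               # ps between frames

    def __post_init__(self) -> None:
        if self.nx * self.ny < 12:
            raise SpecError("membrane lattice needs nx*ny >= 12")
        if self.spacing <= 0:
            raise SpecError("spacing must be positive")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        self.radius_series = np.asarray(self.radius_series, dtype=float)
        if len(self.radius_series) < 1:
            raise SpecError("radius_series must have at least one frame")
        half_extent = (self.nx - 1) * self.spacing / 2.0
        finite = self.radius_series[np.isfinite(self.radius_series)]
        if finite.size and finite.min() < half_extent:
            raise SpecError(
                f"bend radius {finite.min():g} Å is smaller than the half "
                f"patch extent {half_extent:g} Å; the patch would wrap"
            )


@dataclass
class DimerSpec:
    """Kinked two-chain pseudo-dimer of Cα traces.

    Residue numbering mirrors the construct analysed (residues 19–239,
    kink at VAL114, core ARG92–VAL114, arm VAL114–SER157).
    """

    residues_per_chain: int = 221
    start_residue: int = 19
    kink_residue: int = 114
    arm_range: tuple[int, int] = (114, 157)
    core_range: tuple[int, int] = (92, 114)
    helix_rise: float = 1.5         # Å per residue
    helix_radius: float = 2.3       # Å
    twist_deg: float = 100.0        # per residue
    kink_angle_deg: float = 40.0    # static kink magnitude
    chain_gap: float = 4.0          # Å between the two chain starts
    arm_angle_series: np.ndarray | None = None  # (n,) or (n, 2) degrees
    noise_sd: float = 0.0           # Å, per-atom isotropic
    seed: int = 0

    def __post_init__(self) -> None:
        last = self.start_residue + self.residues_per_chain - 1
        if not (self.start_residue < self.kink_residue < last):
            raise SpecError("kink_residue must lie strictly inside the chain")
        if self.core_range[1] != self.kink_residue or self.arm_range[0] != self.kink_residue:
            raise SpecError("arm and core ranges must share exactly the kink residue")
        if self.arm_angle_series is not None:
            self.arm_angle_series = np.atleast_1d(
                np.asarray(self.arm_angle_series, dtype=float))


@dataclass
class MotionSpec:
    """Stochastic/deterministic driver for the arm swing.

    ``amplitude`` is the stationary standard deviation (OU) or the peak
    (sinusoid) of the shared pitch, in degrees.  ``correlation_alpha_d``
    plants a target Pearson correlation between α and the span d; when
    unset the two chains swing independently and no breathing noise is
    added.  ``core_amplitude`` drives independent core-segment jitter so
    β decorrelates from d.
    """

    n_frames: int = 1000
    dt: float = 100.0               # ps
    process: str = "ou"             # {"ou", "sinusoid"}
    amplitude: float = 5.0          # degrees
    correlation_alpha_d: float | None = None
    core_amplitude: float = 2.0     # degrees
    ou_tau: float = 10.0            # frames, OU relaxation time
    sinusoid_period: float = 100.0  # frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise SpecError("n_frames must be >= 2")
        if self.amplitude < 0:
            raise SpecError("amplitude must be >= 0")
        if self.process not in ("ou", "sinusoid"):
            raise SpecError(f"unknown process {self.process!r}")
        if self.correlation_alpha_d is not None and not (
                -1.0 <= self.correlation_alpha_d <= 1.0):
            raise SpecError("correlation_alpha_d must be in [-1, 1]")


@dataclass
class GroundTruth:
    """Per-frame planted values for the downstream estimators."""

    kappa_nm: np.ndarray | None = None     # true curvature, nm^-1
    alpha_deg: np.ndarray | None = None
    beta_deg: np.ndarray | None = None
    gamma_deg: np.ndarray | None = None
    d_A: np.ndarray | None = None
    bonded_donor_residues: list[int] = field(default_factory=list)
    nonbonded_donor_residues: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {}
        for k in ("kappa_nm", "alpha_deg", "beta_deg", "gamma_deg", "d_A"):
            v = getattr(self, k)
            if v is not None:
                out[k] = np.asarray(v).tolist()
        if self.bonded_donor_residues:
            out["bonded_donor_residues"] = list(self.bonded_donor_residues)
        if self.nonbonded_donor_residues:
            out["nonbonded_donor_residues"] = list(self.nonbonded_donor_residues)
        return out


# ---------------------------------------------------------------------------
# membrane
# ---------------------------------------------------------------------------

def generate_membrane_trajectory(spec: MembraneSpec) -> tuple[Trajectory, GroundTruth]:
    """Bend a phosphorus lattice toward R(t) with additive noise.

    Frame t maps the flat lattice coordinate s (an arc length) onto a
    cylinder bent along x:  x = R sin(s/R), z = R (cos(s/R) − cos(S/R))
    with S the half patch extent, i.e. an upward dome with its apex over
    the center and its edges at z = 0, bulging toward +z (the protein
    side).  The apex height is the sagitta R (1 − cos(S/R)) of the bent
    patch.  κ*(t) = 10/R(t) in nm⁻¹; flat frames have κ* = 0.
    """
    rng = np.random.default_rng(spec.seed)
    xs = (np.arange(spec.nx) - (spec.nx - 1) / 2.0) * spec.spacing
    ys = (np.arange(spec.ny) - (spec.ny - 1) / 2.0) * spec.spacing
    sx, sy = np.meshgrid(xs, ys, indexing="ij")
    sx, sy = sx.ravel(), sy.ravel()
    half_extent = (spec.nx - 1) * spec.spacing / 2.0
    n = sx.size

    topology = [
        Atom(serial=i + 1, name="P", element="P", residue_name="POP",
             residue_number=i + 1, chain_id="M")
        for i in range(n)
    ]
    frames, kappa = [], []
    for t, R in enumerate(np.asarray(spec.radius_series, dtype=float)):
        if np.isinf(R):
            coords = np.column_stack([sx, sy, np.zeros(n)])
            kappa.append(0.0)
        else:
            theta = sx / R
            coords = np.column_stack([R * np.sin(theta), sy,
                                      R * (np.cos(theta)
                                           - np.cos(half_extent / R))])
            kappa.append(10.0 / R)
        if spec.noise_sd > 0:
            coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
        frames.append(Frame(time=t * spec.dt, coords=coords))
    truth = GroundTruth(kappa_nm=np.array(kappa))
    return Trajectory(topology=topology, frames=frames), truth


# ---------------------------------------------------------------------------
# helices and the pseudo-dimer
# ---------------------------------------------------------------------------

def _elevate(theta_rad: float) -> np.ndarray:
    """Rotation about lab y mapping +x toward +z by *theta* (elevation)."""
    c, s = np.cos(theta_rad), np.sin(theta_rad)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def _ideal_helix(residues: np.ndarray, rise: float, radius: float,
                 twist_deg: float, x0: float = 0.0) -> np.ndarray:
    """Cα positions of an ideal helix with its axis along +x."""
    k = residues - residues[0]
    phi = np.deg2rad(twist_deg) * k
    return np.column_stack([x0 + k * rise,
                            radius * np.cos(phi),
                            radius * np.sin(phi)])


def _apply_kinks(pos: np.ndarray, residues: np.ndarray,
                 kinks: Sequence[tuple[int, float]]) -> np.ndarray:
    """Rotate all residues downstream of each kink about its hinge Cα."""
    out = pos.copy()
    for kres, ang in sorted(kinks):
        hinge = out[residues == kres][0]
        mask = residues > kres
        E = _elevate(np.deg2rad(ang))
        out[mask] = hinge + (out[mask] - hinge) @ E.T
    return out


def generate_kinked_helix(start_residue: int, end_residue: int,
                          kinks: Sequence[tuple[int, float]] = (),
                          rise: float = 1.5, radius: float = 2.3,
                          twist_deg: float = 100.0, noise_sd: float = 0.0,
                          seed: int = 0, chain_id: str = "A") -> Trajectory:
    """Single-frame, single-chain Cα helix with planted kinks.

    ``kinks`` is a list of (residue, bend_angle_deg); each bend rotates
    everything C-terminal of that residue about its Cα, cumulatively.
    """
    residues = np.arange(start_residue, end_residue + 1)
    pos = _ideal_helix(residues, rise, radius, twist_deg)
    pos = _apply_kinks(pos, residues, kinks)
    if noise_sd > 0:
        pos = pos + np.random.default_rng(seed).normal(0, noise_sd, pos.shape)
    topology = [
        Atom(serial=i + 1, name="CA", element="C", residue_name="ALA",
             residue_number=int(r), chain_id=chain_id)
        for i, r in enumerate(residues)
    ]
    return Trajectory(topology=topology, frames=[Frame(time=0.0, coords=pos)])


def _ou_series(rng: np.random.Generator, n: int, sd: float, tau: float) -> np.ndarray:
    """Stationary Ornstein–Uhlenbeck path via its exact AR(1) discretization."""
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-1.0 / tau)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), size=n - 1)
    for t in range(1, n):
        x[t] = a * x[t - 1] + innov[t - 1]
    return x


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


_MIRROR = np.diag([-1.0, 1.0, 1.0])


def _dimer_motion(spec: DimerSpec, motion: MotionSpec | None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Resolve per-frame (pitch_A, pitch_B, core jitter (n,2), breathe u)."""
    if spec.arm_angle_series is not None:
        s = spec.arm_angle_series
        if s.ndim == 1:
            pa = pb = s
        else:
            pa, pb = s[:, 0], s[:, 1]
        n = len(pa)
        return pa, pb, np.zeros((n, 2)), np.zeros(n), n

    if motion is None:
        raise SpecError("either arm_angle_series or a MotionSpec is required")
    n = motion.n_frames
    rng = np.random.default_rng(motion.seed)

    def draw(sd: float) -> np.ndarray:
        if motion.process == "sinusoid":
            phase = rng.uniform(0, 2 * np.pi)
            return sd * np.sin(2 * np.pi * np.arange(n) / motion.sinusoid_period
                               + phase)
        return _ou_series(rng, n, sd, motion.ou_tau)

    core = np.column_stack([draw(motion.core_amplitude),
                            draw(motion.core_amplitude)])
    rho = motion.correlation_alpha_d
    if rho is None:
        return draw(motion.amplitude), draw(motion.amplitude), core, np.zeros(n), n

    # shared pitch moves alpha AND d; symmetric x-translation ("breathing")
    # moves d only.  Small-angle mixing sets the breathing amplitude.
    shared = draw(motion.amplitude)
    arm_len = (spec.arm_range[1] - spec.arm_range[0]) * spec.helix_rise
    dd_ds = 2.0 * arm_len * np.sin(np.deg2rad(spec.kink_angle_deg))  # Å/rad
    sigma_d_pitch = dd_ds * np.deg2rad(motion.amplitude)
    if abs(rho) < 1e-12:
        sigma_u = 10.0 * sigma_d_pitch  # drown the pitch signal
    else:
        sigma_u = 0.5 * sigma_d_pitch * np.sqrt(max(1.0 / rho**2 - 1.0, 0.0))
    breathe = _ou_series(rng, n, sigma_u, motion.ou_tau)
    return shared, shared, core, breathe, n


def generate_dimer_trajectory(spec: DimerSpec, motion: MotionSpec | None = None
                              ) -> tuple[Trajectory, GroundTruth]:
    """Build the swinging pseudo-dimer and its planted α/β/γ/d series.

    Returns the trajectory (chains A and B, Cα only) and ground truth
    computed from the same rotation matrices that built the frames.
    """
    first = spec.start_residue
    last = first + spec.residues_per_chain - 1
    residues = np.arange(first, last + 1)
    base = _ideal_helix(residues, spec.helix_rise, spec.helix_radius,
                        spec.twist_deg, x0=spec.chain_gap / 2.0)
    kink_mask = residues > spec.kink_residue
    core_mask = (residues >= spec.core_range[0]) & (residues < spec.kink_residue)
    hinge = base[residues == spec.kink_residue][0]
    anchor_res = spec.arm_range[1]
    g_lo, g_hi = spec.core_range[0], spec.arm_range[1]  # Helix-2 union range

    pa, pb, core, breathe, n_frames = _dimer_motion(spec, motion)
    dt = motion.dt if motion is not None else 100.0
    rng = np.random.default_rng(spec.seed)

    topology: list[Atom] = []
    for chain in ("A", "B"):
        for i, r in enumerate(residues):
            topology.append(Atom(serial=len(topology) + 1, name="CA",
                                 element="C", residue_name="ALA",
                                 residue_number=int(r), chain_id=chain))

    frames = []
    alpha = np.empty(n_frames)
    beta = np.empty(n_frames)
    gamma = np.empty(n_frames)
    span = np.empty(n_frames)
    kink0 = spec.kink_angle_deg
    x_hat = np.array([1.0, 0.0, 0.0])

    for t in range(n_frames):
        per_chain = []
        arm_dirs, core_dirs, chords, anchors = [], [], [], []
        for ci, (pitch, cj) in enumerate(((pa[t], core[t, 0]),
                                          (pb[t], core[t, 1]))):
            pos = base.copy()
            E_arm = _elevate(np.deg2rad(kink0 + pitch))
            pos[kink_mask] = hinge + (base[kink_mask] - hinge) @ E_arm.T
            E_core = _elevate(np.deg2rad(cj))
            pos[core_mask] = hinge + (base[core_mask] - hinge) @ E_core.T
            shift = np.array([breathe[t], 0.0, 0.0])
            pos = pos + shift
            u_arm = E_arm @ x_hat
            u_core = E_core @ x_hat
            chord = (pos[residues == g_hi][0] - pos[residues == g_lo][0])
            anchor = pos[residues == anchor_res][0]
            if ci == 1:  # chain B is the mirror image
                pos = pos @ _MIRROR.T
                u_arm = _MIRROR @ u_arm
                u_core = _MIRROR @ u_core
                chord = _MIRROR @ chord
                anchor = _MIRROR @ anchor
            per_chain.append(pos)
            arm_dirs.append(u_arm)
            core_dirs.append(u_core)
            chords.append(chord)
            anchors.append(anchor)

        coords = np.vstack(per_chain)
        if spec.noise_sd > 0:
            coords = coords + rng.normal(0, spec.noise_sd, coords.shape)
        frames.append(Frame(time=t * dt, coords=coords))
        alpha[t] = _angle_deg(arm_dirs[0], arm_dirs[1])
        beta[t] = _angle_deg(core_dirs[0], core_dirs[1])
        gamma[t] = _angle_deg(chords[0], chords[1])
        span[t] = float(np.linalg.norm(anchors[0] - anchors[1]))

    traj = Trajectory(topology=topology, frames=frames)
    _check_self_intersection(traj, residues, spec)
    truth = GroundTruth(alpha_deg=alpha, beta_deg=beta, gamma_deg=gamma, d_A=span)
    return traj, truth


def _check_self_intersection(traj: Trajectory, residues: np.ndarray,
                             spec: DimerSpec) -> None:
    """Reject arm rotations that fold the arm back into the chain (<1 Å)."""
    n = len(residues)
    arm_local = np.flatnonzero(residues > spec.kink_residue + 1)
    rest_local = np.flatnonzero(residues < spec.kink_residue - 1)
    if not len(arm_local) or not len(rest_local):
        return
    # worst frame suffices: arm deflection is a rigid rotation, so the
    # minimum clearance is monotone in the deflection magnitude
    for chain_off in (0, n):
        lo = np.inf
        worst = None
        for fr in traj.frames:
            arm = fr.coords[arm_local + chain_off]
            rest = fr.coords[rest_local + chain_off]
            d = cdist(arm, rest).min()
            if d < lo:
                lo, worst = d, fr.time
        if lo < 1.0:
            raise SpecError(
                f"arm rotation causes self-intersection (min contact "
                f"{lo:.2f} Å at t={worst:g} ps)"
            )


# ---------------------------------------------------------------------------
# interaction fixtures
# ---------------------------------------------------------------------------

def generate_hbond_fixture(n_bonded: int, n_nonbonded: int, seed: int = 0
                           ) -> Trajectory:
    """Plant donor–H–acceptor triples: bonded at D···A = 2.8 Å, non-bonded
    at 5.0 Å, both near-linear, spaced 20 Å apart along x.

    Donors are LYS NZ/HZ on chain A (residues 1..n in planting order,
    bonded first); acceptors are PIP O1 on chain L with matching residue
    numbers.
    """
    if n_bonded < 0 or n_nonbonded < 0:
        raise SpecError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    topology: list[Atom] = []
    coords: list[np.ndarray] = []

    def add(triple_idx: int, da: float) -> None:
        base = np.array([20.0 * triple_idx, 0.0, 0.0])
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        resnum = triple_idx + 1
        for name, element, chain, resname, pos in (
                ("NZ", "N", "A", "LYS", base),
                ("HZ", "H", "A", "LYS", base + 1.0 * u),
                ("O1", "O", "L", "PIP", base + da * u)):
            topology.append(Atom(serial=len(topology) + 1, name=name,
                                 element=element, residue_name=resname,
                                 residue_number=resnum, chain_id=chain))
            coords.append(pos)

    for k in range(n_bonded):
        add(k, 2.8)
    for k in range(n_nonbonded):
        add(n_bonded + k, 5.0)
    if not topology:  # degenerate but valid request
        topology = [Atom(1, "NZ", "N", "LYS", 1, "A")]
        coords = [np.zeros(3)]
    return Trajectory(topology=topology,
                      frames=[Frame(time=0.0, coords=np.array(coords))])


def generate_sphere_fixture(r1: float, r2: float, center_distance: float
                            ) -> tuple[Trajectory, dict[str, float]]:
    """Two single-atom bodies with assigned van der Waals radii.

    Returns the trajectory and the radii table ({"Q1": r1, "Q2": r2})
    to pass to SASAParams.
    """
    if r1 <= 0 or r2 <= 0:
        raise SpecError("radii must be positive")
    topology = [
        Atom(serial=1, name="Q1", element="Q1", residue_name="SPH",
             residue_number=1, chain_id="A"),
        Atom(serial=2, name="Q2", element="Q2", residue_name="SPH",
             residue_number=1, chain_id="B"),
    ]
    coords = np.array([[0.0, 0.0, 0.0], [center_distance, 0.0, 0.0]])
    traj = Trajectory(topology=topology,
                      frames=[Frame(time=0.0, coords=coords)])
    return traj, {"Q1": r1, "Q2": r2}


# ---------------------------------------------------------------------------
# assembly and serialization
# ---------------------------------------------------------------------------

def place_dimer_on_membrane(membrane: Trajectory, dimer: Trajectory,
                            z_offset: float = 20.0) -> Trajectory:
    """Concatenate membrane and dimer atoms, lifting the dimer by z_offset.

    Frame counts must match; times are taken from the membrane.
    """
    if membrane.n_frames != dimer.n_frames:
        raise SpecError(
            f"frame counts differ: membrane {membrane.n_frames}, "
            f"dimer {dimer.n_frames}"
        )
    topology = list(membrane.topology)
    for a in dimer.topology:
        topology.append(Atom(serial=len(topology) + 1, name=a.name,
                             element=a.element, residue_name=a.residue_name,
                             residue_number=a.residue_number,
                             chain_id=a.chain_id))
    shift = np.array([0.0, 0.0, z_offset])
    frames = [
        Frame(time=mf.time, coords=np.vstack([mf.coords, df.coords + shift]))
        for mf, df in zip(membrane.frames, dimer.frames)
    ]
    return Trajectory(topology=topology, frames=frames)


def write_bundle(trajectory: Trajectory, truth: GroundTruth,
                 directory: str | Path, prefix: str = "synthetic") -> dict[str, Path]:
    """Write coord_table CSV + topology PDB + JSON ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "coords": directory / f"{prefix}_coords.csv",
        "topology": directory / f"{prefix}_topology.pdb",
        "truth": directory / f"{prefix}_truth.json",
    }
    write_coord_table(trajectory, paths["coords"])
    from .trajectory import write_pdb
    write_pdb(Trajectory(topology=trajectory.topology,
                         frames=[trajectory.frames[0]]), paths["topology"])
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1))
    return paths
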