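"""SASA, protein–protein interaction area, and geometric hydrogen bonds.

The solvent-accessible surface area is computed with the Shrake–Rupley
construction: each atom's van der Waals sphere is inflated by the probe
radius (water, 1.4 Å) and sampled with a deterministic quasi-uniform
Fibonacci point set; a sample point is accessible when it lies outside
every other inflated sphere of the body.  The per-partner buried area
of a complex is

    S_interaction = (SASA_A + SASA_B − SASA_AB) / 2

computed from three SASA evaluations (each body alone, then the
complex).  Point-sampling noise can make a near-zero area marginally
negative; such values are clamped to 0 and flagged.

Hydrogen bonds are geometric: a donor–hydrogen–acceptor triple with
D···A ≤ 3.5 Å and an H–D–A angle ≤ 30° (the convention of standard MD
analysis tools; both cutoffs inclusive and configurable).  For
hydrogen-free topologies (coarse Cα fixtures) a distance-only mode
applies the D···A cutoff alone and labels itself in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .trajectory import Atom, Frame, Selection, Trajectory

__all__ = [
    "BONDI_RADII",
    "SASAParams",
    "InteractionAreaResult",
    "HBondCriteria",
    "ResidueGroup",
    "HBond",
    "HBondSeries",
    "sasa",
    "interaction_area",
    "detect_hbonds",
    "grouped_hbond_series",
]

# Bondi van der Waals radii (Å)
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


@dataclass
class SASAParams:
    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii_table: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ConfigurationError("probe_radius must be positive")
        if self.n_sphere_points < 100:
            raise ConfigurationError("n_sphere_points must be >= 100")

    def radius_of(self, element: str) -> float:
        r = self.radii_table.get(element) or self.radii_table.get(element.upper())
        if r is None:
            raise ConfigurationError(
                f"no van der Waals radius for element {element!r}")
        return r


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(topology: Sequence[Atom], frame: Frame, body: Sequence[int],
         params: SASAParams | None = None) -> float:
    """Shrake–Rupley solvent-accessible surface area of *body* (Å²).

    Only atoms inside *body* occlude each other; anything else in the
    topology is ignored (that is what makes the complex/monomer SASA
    triple of the interaction area meaningful).
    """
    params = params or SASAParams()
    body = np.asarray(body, dtype=int)
    if len(body) == 0:
        raise ConfigurationError("SASA body must be non-empty")
    centers = frame.coords[body]
    radii = np.array([params.radius_of(topology[i].element) for i in body])
    expanded = radii + params.probe_radius
    unit = _fibonacci_sphere(params.n_sphere_points)

    tree = cKDTree(centers)
    max_r = expanded.max()
    total = 0.0
    for i in range(len(body)):
        pts = centers[i] + expanded[i] * unit
        neigh = [j for j in tree.query_ball_point(centers[i],
                                                  expanded[i] + max_r)
                 if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - centers[j], axis=1)
            exposed &= d >= expanded[j] - 1e-10
        total += 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return float(total)


@dataclass
class InteractionAreaResult:
    """SASA triple and the per-partner buried area (Å²)."""

    sasa_A: float
    sasa_B: float
    sasa_AB: float
    area: float
    clamped: bool = False


def interaction_area(topology: Sequence[Atom], frame: Frame,
                     body_A: Sequence[int], body_B: Sequence[int],
                     params: SASAParams | None = None) -> InteractionAreaResult:
    """Per-partner buried area (SASA_A + SASA_B − SASA_AB) / 2.

    Exactly symmetric in A and B.  Small negative values arising from
    point-sampling noise are clamped to 0 with a warning.
    """
    a = np.asarray(body_A, dtype=int)
    b = np.asarray(body_B, dtype=int)
    if np.intersect1d(a, b).size:
        raise ConfigurationError("body_A and body_B must be disjoint")
    params = params or SASAParams()
    s_a = sasa(topology, frame, a, params)
    s_b = sasa(topology, frame, b, params)
    s_ab = sasa(topology, frame, np.concatenate([a, b]), params)
    area = (s_a + s_b - s_ab) / 2.0
    clamped = False
    if area < 0:
        if area < -1.0:
            warnings.warn(f"interaction area {area:.2f} Å² is substantially "
                          "negative; check the bodies", stacklevel=2)
        area, clamped = 0.0, True
    return InteractionAreaResult(sasa_A=s_a, sasa_B=s_b, sasa_AB=s_ab,
                                 area=area, clamped=clamped)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HBondCriteria:
    """Geometric cutoffs; both inclusive.

    ``angle_cutoff`` is the hydrogen–donor–acceptor angle (deviation
    from a linear D–H···A arrangement measured at the donor).
    """

    da_cutoff: float = 3.5           # Å
    angle_cutoff: float = 30.0       # degrees
    dh_bond_max: float = 1.25        # Å, geometric D–H attachment search

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ConfigurationError("hydrogen-bond cutoffs must be positive")


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int | None
    acceptor: int


def _attached_hydrogens(topology: Sequence[Atom], frame: Frame,
                        donors: np.ndarray, max_dist: float) -> dict[int, list[int]]:
    h_idx = np.array([i for i, a in enumerate(topology) if a.element == "H"],
                     dtype=int)
    out: dict[int, list[int]] = {int(d): [] for d in donors}
    if len(h_idx) == 0:
        return out
    tree = cKDTree(frame.coords[h_idx])
    for d in donors:
        near = tree.query_ball_point(frame.coords[d], max_dist)
        out[int(d)] = [int(h_idx[k]) for k in near]
    return out


def detect_hbonds(topology: Sequence[Atom], frame: Frame,
                  donors: Sequence[int], acceptors: Sequence[int],
                  criteria: HBondCriteria | None = None) -> list[HBond]:
    """Geometric donor→acceptor hydrogen bonds in one frame.

    When the topology contains hydrogens, a bond is a (D, H, A) triple
    with D···A ≤ cutoff and angle(H–D–A) ≤ cutoff; donors without an
    attached hydrogen cannot donate.  Without any hydrogens the
    distance-only criterion applies (hydrogen recorded as None).
    Intra-residue pairs are skipped.
    """
    criteria = criteria or HBondCriteria()
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if len(donors) == 0 or len(acceptors) == 0:
        return []

    has_h = any(a.element == "H" for a in topology)
    h_map = (_attached_hydrogens(topology, frame, donors, criteria.dh_bond_max)
             if has_h else {})
    acc_tree = cKDTree(frame.coords[acceptors])
    bonds: list[HBond] = []
    for d in donors:
        da = topology[d]
        near = acc_tree.query_ball_point(frame.coords[d],
                                         criteria.da_cutoff + 1e-9)
        for k in near:
            a_idx = int(acceptors[k])
            aa = topology[a_idx]
            if (da.chain_id, da.residue_number) == (aa.chain_id, aa.residue_number):
                continue
            dist = float(np.linalg.norm(frame.coords[a_idx] - frame.coords[d]))
            if dist > criteria.da_cutoff + 1e-9:
                continue
            if not has_h:
                bonds.append(HBond(donor=int(d), hydrogen=None, acceptor=a_idx))
                continue
            for h in h_map.get(int(d), []):
                vh = frame.coords[h] - frame.coords[d]
                va = frame.coords[a_idx] - frame.coords[d]
                cosang = np.dot(vh, va) / (np.linalg.norm(vh) * np.linalg.norm(va))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang <= criteria.angle_cutoff + 1e-9:
                    bonds.append(HBond(donor=int(d), hydrogen=int(h),
                                       acceptor=a_idx))
                    break
    return bonds


@dataclass(frozen=True)
class ResidueGroup:
    """Named cluster of residues, e.g. the charged patches on the concave
    face: group 1 (ARG19, LYS23), group 2 (LYS47, ARG48, LYS132)."""

    name: str
    members: tuple[tuple[str, int, str], ...]   # (chain, resnum, resname)

    def __post_init__(self):
        if not self.members:
            raise ConfigurationError(f"group {self.name!r} has no members")

    def validate(self, topology: Sequence[Atom]) -> None:
        keys = {(a.chain_id, a.residue_number, a.residue_name) for a in topology}
        missing = [m for m in self.members if tuple(m) not in keys]
        if missing:
            raise ConfigurationError(
                f"group {self.name!r}: members absent from topology: {missing}")

    def residue_keys(self) -> set[tuple[str, int]]:
        return {(c, r) for c, r, _ in self.members}


@dataclass
class HBondSeries:
    """Per-frame bond lists with total, per-group and per-lipid counts."""

    times: np.ndarray
    bonds: list[list[HBond]]
    total: np.ndarray
    by_group: dict[str, np.ndarray]
    by_lipid_resname: dict[str, np.ndarray]
    distance_only: bool

    def to_dataframe(self) -> pd.DataFrame:
        data = {"frame": np.arange(len(self.times)), "time_ps": self.times,
                "total": self.total}
        for g, v in self.by_group.items():
            data[f"group_{g}"] = v
        for rn, v in self.by_lipid_resname.items():
            data[f"lipid_{rn}"] = v
        return pd.DataFrame(data)


def grouped_hbond_series(trajectory: Trajectory,
                         groups: Sequence[ResidueGroup],
                         lipid_selection: Selection,
                         criteria: HBondCriteria | None = None) -> HBondSeries:
    """Protein→lipid hydrogen bonds per frame, grouped by residue cluster.

    Donors are all N/O atoms outside the lipid selection; acceptors are
    all N/O atoms inside it.  Counts are reported in total, per
    configured group (by donor residue), and per lipid residue name
    (the headgroup-type partition).
    """
    criteria = criteria or HBondCriteria()
    topo = trajectory.topology
    for g in groups:
        g.validate(topo)
    lipid_idx = set(lipid_selection.resolve(topo).tolist())
    if not lipid_idx:
        raise ConfigurationError("lipid selection resolves to no atoms")

    donors = np.array([i for i, a in enumerate(topo)
                       if i not in lipid_idx and a.element in ("N", "O")],
                      dtype=int)
    acceptors = np.array([i for i in sorted(lipid_idx)
                          if topo[i].element in ("N", "O")], dtype=int)
    has_h = any(a.element == "H" for a in topo)

    group_keys = {g.name: g.residue_keys() for g in groups}
    lipid_resnames = sorted({topo[i].residue_name for i in acceptors})
    n = trajectory.n_frames
    total = np.zeros(n, dtype=int)
    by_group = {g: np.zeros(n, dtype=int) for g in group_keys}
    by_lipid = {rn: np.zeros(n, dtype=int) for rn in lipid_resnames}
    all_bonds: list[list[HBond]] = []

    for t, fr in enumerate(trajectory.frames):
        bonds = detect_hbonds(topo, fr, donors, acceptors, criteria)
        all_bonds.append(bonds)
        total[t] = len(bonds)
        for b in bonds:
            dk = (topo[b.donor].chain_id, topo[b.donor].residue_number)
            for gname, keys in group_keys.items():
                if dk in keys:
                    by_group[gname][t] += 1
            by_lipid[topo[b.acceptor].residue_name][t] += 1
    return HBondSeries(times=trajectory.times, bonds=all_bonds, total=total,
                       by_group=by_group, by_lipid_resname=by_lipid,
                       distance_only=not has_h)
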