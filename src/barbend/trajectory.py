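"""Structures, coordinate trajectories and atom selection.

The internal length unit is the ångström everywhere.  GRO files (nm) are
scaled by 10 on read; PDB coordinates are taken as Å.  Curvature is
converted to nm⁻¹ only at the reporting layer (``membrane`` module).

Three trajectory dialects are supported:

``multi_model_pdb``
    Standard PDB with MODEL/ENDMDL records, one frame per model.
``gro_series``
    Concatenated GRO blocks in a single file, one frame per block; the
    frame time is parsed from a ``t= <ps>`` token on the title line when
    present.
``coord_table``
    A plain CSV with header ``frame,time_ps,atom_index,x,y,z`` (Å).  This
    is the canonical, bit-exact test format; the synthetic generators
    write it.

Addressing is PDB-like: chains are single letters, residue numbers are
1-based, and residue ranges are inclusive at both ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, StructureError

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "Selection",
    "read_structure",
    "read_trajectory",
    "select",
    "write_coord_table",
    "write_pdb",
]


@dataclass(frozen=True)
class Atom:
    """One atom of the topology; identity only, no coordinates."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str


@dataclass
class Frame:
    """Coordinates (Å) for every topology atom at one time point (ps)."""

    time: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise StructureError(
                f"frame coords must be (n, 3); got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("frame contains non-finite coordinates")


@dataclass
class Trajectory:
    """A topology plus one or more frames with consistent atom counts."""

    topology: list[Atom]
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise StructureError(
                    f"frame {i} has {fr.coords.shape[0]} atoms, topology has {n}"
                )
        times = [fr.time for fr in self.frames]
        if any(b < a for a, b in zip(times, times[1:])):
            raise StructureError("frame times must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def coords(self) -> np.ndarray:
        """All coordinates as an (n_frames, n_atoms, 3) array."""
        return np.stack([fr.coords for fr in self.frames])


@dataclass(frozen=True)
class Selection:
    """Declarative atom predicate resolving to topology-ordered indices.

    All criteria are ANDed; a criterion left ``None`` matches everything.
    ``residue_range`` is inclusive at both ends, 1-based, as in the PDB.
    """

    chain_id: str | None = None
    residue_range: tuple[int, int] | None = None
    residue_names: frozenset[str] | None = None
    atom_names: frozenset[str] | None = None

    def __post_init__(self):
        # allow plain iterables at construction
        for f in ("residue_names", "atom_names"):
            v = getattr(self, f)
            if v is not None and not isinstance(v, frozenset):
                object.__setattr__(self, f, frozenset(v))

    def resolve(self, topology: Sequence[Atom]) -> np.ndarray:
        idx = []
        lo, hi = self.residue_range if self.residue_range else (None, None)
        for i, a in enumerate(topology):
            if self.chain_id is not None and a.chain_id != self.chain_id:
                continue
            if lo is not None and not (lo <= a.residue_number <= hi):
                continue
            if self.residue_names is not None and a.residue_name not in self.residue_names:
                continue
            if self.atom_names is not None and a.name not in self.atom_names:
                continue
            idx.append(i)
        return np.array(idx, dtype=int)


def select(trajectory: Trajectory, selection: Selection) -> np.ndarray:
    """Resolve *selection* against the trajectory topology.

    Deterministic and order-stable: indices come back in topology order.
    An empty result is valid; downstream operations decide whether that
    is an error.
    """
    return selection.resolve(trajectory.topology)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _element_from_name(name: str) -> str:
    stripped = re.sub(r"[^A-Za-z]", "", name)
    return stripped[:1].upper() if stripped else "X"


def _parse_pdb_atom(line: str, lineno: int) -> tuple[Atom, tuple[float, float, float]]:
    if len(line.rstrip("\n")) < 54:
        raise ParseError(
            f"line {lineno}: truncated ATOM/HETATM record "
            f"({len(line.rstrip())} columns, need >= 54)",
            line_number=lineno,
        )
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or "X"
        residue_number = int(line[22:26])
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError as exc:
        raise ParseError(f"line {lineno}: malformed ATOM record ({exc})",
                         line_number=lineno) from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    atom = Atom(serial=serial, name=name,
                element=element or _element_from_name(name),
                residue_name=residue_name, residue_number=residue_number,
                chain_id=chain_id)
    return atom, xyz


def _read_pdb(path: Path, multi_model: bool) -> Trajectory:
    topology: list[Atom] = []
    frames: list[Frame] = []
    cur: list[tuple[float, float, float]] = []
    model_open = False
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                model_open = True
                cur = []
            elif rec in ("ATOM", "HETATM"):
                atom, xyz = _parse_pdb_atom(line, lineno)
                if not frames:
                    topology.append(atom)
                cur.append(xyz)
            elif rec == "ENDMDL":
                model_open = False
                frames.append(Frame(time=float(len(frames)), coords=np.array(cur)))
                if len(frames) > 1 and frames[-1].coords.shape[0] != frames[0].coords.shape[0]:
                    raise StructureError(
                        f"model {len(frames)} has {frames[-1].coords.shape[0]} atoms, "
                        f"model 1 has {frames[0].coords.shape[0]}"
                    )
                cur = []
                if not multi_model:
                    break
    if cur and (model_open or not frames):
        frames.append(Frame(time=float(len(frames)), coords=np.array(cur)))
    if not frames:
        raise ParseError(f"{path}: no ATOM records found")
    if not saw_model or not multi_model:
        frames = frames[:1]
    return Trajectory(topology=topology, frames=frames)


def write_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write all frames as a (multi-)model PDB; coordinates to 3 decimals."""
    with open(path, "w") as fh:
        multi = trajectory.n_frames > 1
        for m, fr in enumerate(trajectory.frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for a, (x, y, z) in zip(trajectory.topology, fr.coords):
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {a.serial % 100000:5d} {name:<4.4s} {a.residue_name:<3.3s} "
                    f"{a.chain_id[:1]}{a.residue_number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                    f"{a.element:>2.2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def _read_gro_block(lines: list[str], start: int) -> tuple[list[Atom], np.ndarray, float, int]:
    """Parse one GRO frame starting at ``lines[start]``; returns next index."""
    title = lines[start]
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else np.nan
    try:
        natoms = int(lines[start + 1].strip())
    except (IndexError, ValueError) as exc:
        raise ParseError(f"line {start + 2}: expected atom count",
                         line_number=start + 2) from exc
    atoms: list[Atom] = []
    coords = np.empty((natoms, 3))
    for k in range(natoms):
        lineno = start + 2 + k
        try:
            line = lines[lineno]
        except IndexError as exc:
            raise ParseError(f"line {lineno + 1}: unexpected end of GRO block",
                             line_number=lineno + 1) from exc
        if len(line.rstrip("\n")) < 44:
            raise ParseError(f"line {lineno + 1}: truncated GRO atom line",
                             line_number=lineno + 1)
        try:
            resnum = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            # GRO stores nm; internal unit is Å
            coords[k] = [float(line[20:28]) * 10.0,
                         float(line[28:36]) * 10.0,
                         float(line[36:44]) * 10.0]
        except ValueError as exc:
            raise ParseError(f"line {lineno + 1}: malformed GRO atom line ({exc})",
                             line_number=lineno + 1) from exc
        atoms.append(Atom(serial=serial, name=name,
                          element=_element_from_name(name),
                          residue_name=resname, residue_number=resnum,
                          chain_id="X"))
    return atoms, coords, time, start + 2 + natoms + 1  # +1 skips the box line


def _read_gro(path: Path, series: bool) -> Trajectory:
    lines = open(path).read().splitlines()
    topology, coords, time, nxt = _read_gro_block(lines, 0)
    frames = [Frame(time=0.0 if np.isnan(time) else time, coords=coords)]
    while series and nxt < len(lines) and lines[nxt].strip():
        atoms, coords, time, nxt = _read_gro_block(lines, nxt)
        if len(atoms) != len(topology):
            raise StructureError(
                f"frame {len(frames)} has {len(atoms)} atoms, frame 0 has {len(topology)}"
            )
        frames.append(Frame(time=float(len(frames)) if np.isnan(time) else time,
                            coords=coords))
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# coord_table (canonical CSV dialect)
# ---------------------------------------------------------------------------

_COORD_COLS = ["frame", "time_ps", "atom_index", "x", "y", "z"]


def write_coord_table(trajectory: Trajectory, path: str | Path) -> None:
    """Write the CSV dialect ``frame,time_ps,atom_index,x,y,z`` (Å).

    Floats are written with shortest round-trip repr, so read-back is
    bit-identical.
    """
    rows = []
    for f, fr in enumerate(trajectory.frames):
        for i, (x, y, z) in enumerate(fr.coords):
            rows.append((f, fr.time, i, x, y, z))
    # %.17g guarantees binary round trip for float64
    pd.DataFrame(rows, columns=_COORD_COLS).to_csv(path, index=False,
                                                   float_format="%.17g")


def _read_coord_table(path: Path, topology: Sequence[Atom] | None) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COORD_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: coord_table missing columns {missing}")
    frames = []
    n_atoms = None
    for fnum, grp in df.groupby("frame", sort=True):
        grp = grp.sort_values("atom_index")
        if n_atoms is None:
            n_atoms = len(grp)
        elif len(grp) != n_atoms:
            raise StructureError(
                f"frame {fnum} has {len(grp)} atoms, frame 0 has {n_atoms}"
            )
        frames.append(Frame(time=float(grp["time_ps"].iloc[0]),
                            coords=grp[["x", "y", "z"]].to_numpy()))
    if topology is None:
        topology = [Atom(serial=i + 1, name="X", element="X", residue_name="UNK",
                         residue_number=i + 1, chain_id="X")
                    for i in range(n_atoms or 0)]
    return Trajectory(topology=list(topology), frames=frames)


# ---------------------------------------------------------------------------
# public readers
# ---------------------------------------------------------------------------

_STRUCTURE_FORMATS = {"pdb", "gro"}
_TRAJECTORY_FORMATS = {"multi_model_pdb", "gro_series", "coord_table"}


def _infer_format(path: Path, allowed: set[str]) -> str:
    suffix = path.suffix.lower().lstrip(".")
    mapping = {"pdb": "pdb", "gro": "gro", "csv": "coord_table"}
    fmt = mapping.get(suffix)
    if fmt == "pdb" and "multi_model_pdb" in allowed:
        fmt = "multi_model_pdb"
    if fmt == "gro" and "gro_series" in allowed:
        fmt = "gro_series"
    if fmt not in allowed:
        raise ParseError(f"cannot infer format of {path}; pass format explicitly")
    return fmt


def read_structure(path: str | Path, format: str | None = None) -> Trajectory:
    """Read a single-frame structure (PDB or GRO)."""
    path = Path(path)
    fmt = format or _infer_format(path, _STRUCTURE_FORMATS)
    if fmt == "pdb":
        return _read_pdb(path, multi_model=False)
    if fmt == "gro":
        return _read_gro(path, series=False)
    raise ParseError(f"unknown structure format {fmt!r}; expected pdb or gro")


def read_trajectory(path: str | Path, format: str | None = None,
                    topology: Trajectory | Sequence[Atom] | None = None) -> Trajectory:
    """Read a multi-frame trajectory.

    For ``coord_table`` input, *topology* (a Trajectory or Atom list)
    supplies atom identities; without it placeholder atoms are used and
    only coordinate-based analyses are possible.
    """
    path = Path(path)
    fmt = format or _infer_format(path, _TRAJECTORY_FORMATS)
    if isinstance(topology, Trajectory):
        topology = topology.topology
    if fmt == "multi_model_pdb":
        return _read_pdb(path, multi_model=True)
    if fmt == "gro_series":
        return _read_gro(path, series=True)
    if fmt == "coord_table":
        return _read_coord_table(path, topology)
    raise ParseError(
        f"unknown trajectory format {fmt!r}; expected multi_model_pdb, "
        "gro_series or coord_table"
    )
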