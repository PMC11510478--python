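"""End-to-end orchestration: align → curvature → geometry → interactions
→ displacement, from one config.

Validation is fail-fast (every selection and residue reference is checked
before any stage runs, with errors aggregated, not first-fail); the
stages themselves are isolated afterwards — a failing stage is recorded
in the report and independent stages still run.  Given the same config,
input and seed the outputs are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .errors import BarbendError
from .trajectory import Selection, Trajectory, read_structure, read_trajectory
from .membrane import (FitRegion, DisplacementSpec, align_frames,
                       curvature_series, horizontal_displacement_series)
from .dimer import (SegmentDef, angle_span_series, correlation_summary,
                    default_segments)
from .interactions import (HBondCriteria, ResidueGroup, SASAParams,
                           grouped_hbond_series, interaction_area)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline",
           "report_render"]

_STAGE_ORDER = ["align", "curvature", "geometry", "interactions", "displacement"]


@dataclass
class RunConfig:
    """Flat, serializable pipeline configuration.

    ``groups`` maps a cluster name to member strings "chain:resnum:resname".
    """

    coords: str | None = None
    topology: str | None = None
    format: str | None = None
    output_dir: str = "barbend_out"
    membrane_atom_name: str = "P"
    dimer_atom_name: str = "CA"
    dimer_chains: tuple[str, str] = ("A", "B")
    region_length_x: float = 160.0
    region_width_y: float = 10.0
    region_anchor: str = "dimer_footprint"
    window_fraction: float = 1.0 / 3.0
    core_range: tuple[int, int] = (92, 114)
    arm_range: tuple[int, int] = (114, 157)
    span_anchor_residue: int = 157
    center_residue: int = 69
    hbond_da_cutoff: float = 3.5
    hbond_angle_cutoff: float = 30.0
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 960
    sasa_max_frames: int = 5
    groups: dict[str, list[str]] = field(default_factory=dict)
    pooling: str = "pooled"
    seed: int = 0
    stages: tuple[str, ...] = tuple(_STAGE_ORDER)

    # -- derived objects ---------------------------------------------------
    def membrane_selection(self) -> Selection:
        return Selection(atom_names=frozenset({self.membrane_atom_name}))

    def dimer_selection(self) -> Selection:
        return Selection(atom_names=frozenset({self.dimer_atom_name}))

    def region(self) -> FitRegion:
        return FitRegion(length_x=self.region_length_x,
                         width_y=self.region_width_y,
                         anchor=self.region_anchor)

    def segments(self) -> list[SegmentDef]:
        return default_segments(chains=tuple(self.dimer_chains),
                                core_range=tuple(self.core_range),
                                arm_range=tuple(self.arm_range))

    def span_anchors(self) -> tuple:
        return tuple((c, self.span_anchor_residue, self.dimer_atom_name)
                     for c in self.dimer_chains)

    def displacement_spec(self) -> DisplacementSpec:
        return DisplacementSpec(
            center_residues=tuple((c, self.center_residue, self.dimer_atom_name)
                                  for c in self.dimer_chains),
            tracked_lipids=self.membrane_selection())

    def hbond_criteria(self) -> HBondCriteria:
        return HBondCriteria(da_cutoff=self.hbond_da_cutoff,
                             angle_cutoff=self.hbond_angle_cutoff)

    def sasa_params(self) -> SASAParams:
        return SASAParams(probe_radius=self.sasa_probe_radius,
                          n_sphere_points=self.sasa_n_points)

    def residue_groups(self) -> list[ResidueGroup]:
        out = []
        for name, members in self.groups.items():
            parsed = []
            for m in members:
                chain, resnum, resname = m.split(":")
                parsed.append((chain, int(resnum), resname))
            out.append(ResidueGroup(name=name, members=tuple(parsed)))
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["dimer_chains"] = list(self.dimer_chains)
        d["core_range"] = list(self.core_range)
        d["arm_range"] = list(self.arm_range)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs = dict(d)
        for k in ("dimer_chains", "core_range", "arm_range", "stages"):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunReport:
    """Machine-readable per-stage outcome plus a config echo."""

    stages: dict[str, dict[str, Any]]
    config: dict[str, Any]
    version: str = __version__

    def to_dict(self) -> dict[str, Any]:
        return {"version": self.version, "config": self.config,
                "stages": self.stages}


def _load(config: RunConfig) -> Trajectory:
    if config.coords is None:
        raise BarbendError("config.coords is required to load a trajectory")
    topo = read_structure(config.topology) if config.topology else None
    return read_trajectory(config.coords, format=config.format, topology=topo)


def validate_config(config: RunConfig, trajectory: Trajectory) -> list[str]:
    """Check every selection/residue reference; aggregate all errors."""
    errors: list[str] = []
    topo = trajectory.topology
    if len(config.membrane_selection().resolve(topo)) == 0 and (
            "curvature" in config.stages or "displacement" in config.stages
            or "align" in config.stages):
        errors.append(
            f"membrane selection (atom name {config.membrane_atom_name!r}) "
            "matches no atoms")
    if len(config.dimer_selection().resolve(topo)) == 0:
        errors.append(
            f"dimer selection (atom name {config.dimer_atom_name!r}) "
            "matches no atoms")
    for seg in config.segments():
        try:
            seg.resolve(topo)
        except BarbendError as exc:
            errors.append(str(exc))
    for chain, resnum, name in config.span_anchors():
        if not any(a.chain_id == chain and a.residue_number == resnum
                   and a.name == name for a in topo):
            errors.append(f"span anchor {chain}:{resnum}:{name} not found")
    for chain, resnum, name in config.displacement_spec().center_residues:
        if not any(a.chain_id == chain and a.residue_number == resnum
                   and a.name == name for a in topo):
            errors.append(f"center atom {chain}:{resnum}:{name} not found")
    try:
        for g in config.residue_groups():
            g.validate(topo)
    except (BarbendError, ValueError) as exc:
        errors.append(str(exc))
    return errors


def run_pipeline(config: RunConfig, trajectory: Trajectory | None = None
                 ) -> RunReport:
    """Run all configured stages; write CSV/JSON outputs; return the report.

    Stage isolation: a failure is recorded with its message and later
    independent stages still run (geometry does not need the membrane,
    so it proceeds even when alignment/curvature fail).
    """
    if trajectory is None:
        trajectory = _load(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict[str, Any]] = {}

    aligned = trajectory
    if "align" in config.stages:
        try:
            aligned = align_frames(trajectory, config.membrane_selection(),
                                   config.dimer_selection())
            stages["align"] = {"status": "ok",
                               "summary": {"n_frames": aligned.n_frames}}
        except BarbendError as exc:
            stages["align"] = {"status": "error", "error": str(exc)}
            aligned = trajectory

    if "curvature" in config.stages:
        try:
            cs = curvature_series(aligned, region=config.region(),
                                  window_fraction=config.window_fraction,
                                  membrane_selection=config.membrane_selection(),
                                  dimer_selection=config.dimer_selection())
            cs.to_dataframe().to_csv(out / "curvature.csv", index=False)
            stages["curvature"] = {"status": "ok", "summary": {
                "window_mean_kappa_nm": cs.window_mean,
                "window_sd_kappa_nm": cs.window_sd,
                "n_excluded": cs.n_excluded}}
        except BarbendError as exc:
            stages["curvature"] = {"status": "error", "error": str(exc)}

    if "geometry" in config.stages:
        try:
            series = angle_span_series(aligned, segments=config.segments(),
                                       span_anchors=config.span_anchors())
            series.to_dataframe().to_csv(out / "geometry.csv", index=False)
            corr = correlation_summary(series, pooling=config.pooling)
            corr.to_csv(out / "correlations.csv", index=False)
            stages["geometry"] = {"status": "ok", "summary": {
                "n_excluded": len(series.excluded_frames),
                "correlations": {f"{r.x}-{r.y}": (None if np.isnan(r.pearson_r)
                                                  else float(r.pearson_r))
                                 for r in corr.itertuples()}}}
        except BarbendError as exc:
            stages["geometry"] = {"status": "error", "error": str(exc)}

    if "interactions" in config.stages:
        try:
            summary: dict[str, Any] = {}
            groups = config.residue_groups()
            if groups:
                hs = grouped_hbond_series(aligned, groups,
                                          config.membrane_selection(),
                                          config.hbond_criteria())
                hs.to_dataframe().to_csv(out / "hbonds.csv", index=False)
                summary["hbond_mean_total"] = float(hs.total.mean())
                summary["hbond_mean_by_group"] = {
                    g: float(v.mean()) for g, v in hs.by_group.items()}
                summary["distance_only"] = hs.distance_only
            # monomer-monomer buried area on a deterministic frame subsample
            ca, cb = config.dimer_chains
            idx_a = Selection(chain_id=ca).resolve(aligned.topology)
            idx_b = Selection(chain_id=cb).resolve(aligned.topology)
            if len(idx_a) and len(idx_b):
                picks = np.unique(np.linspace(0, aligned.n_frames - 1,
                                              min(config.sasa_max_frames,
                                                  aligned.n_frames)).astype(int))
                areas = [interaction_area(aligned.topology, aligned.frames[t],
                                          idx_a, idx_b,
                                          config.sasa_params()).area
                         for t in picks]
                summary["interaction_area_mean_A2"] = float(np.mean(areas))
                summary["interaction_area_frames"] = [int(t) for t in picks]
            if not summary:
                raise BarbendError("no groups configured and no dimer chains "
                                   "found; nothing to compute")
            stages["interactions"] = {"status": "ok", "summary": summary}
        except BarbendError as exc:
            stages["interactions"] = {"status": "error", "error": str(exc)}

    if "displacement" in config.stages:
        try:
            disp = horizontal_displacement_series(aligned,
                                                  config.displacement_spec())
            disp.to_csv(out / "displacement.csv", index=False)
            slope = float(np.polyfit(disp["time_ps"],
                                     disp["mean_distance_A"], 1)[0]) \
                if len(disp) > 1 else 0.0
            stages["displacement"] = {"status": "ok", "summary": {
                "mean_distance_first_A": float(disp["mean_distance_A"].iloc[0]),
                "mean_distance_last_A": float(disp["mean_distance_A"].iloc[-1]),
                "trend_slope_A_per_ps": slope}}
        except BarbendError as exc:
            stages["displacement"] = {"status": "error", "error": str(exc)}

    report = RunReport(stages=stages, config=config.to_dict())
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1,
                                                sort_keys=True))
    (out / "report.md").write_text(report_render(report))
    return report


def report_render(report: RunReport) -> str:
    """Human-readable markdown; numbers match the JSON to printed precision."""
    lines = [f"# Pipeline report (barbend {report.version})", ""]
    for name in _STAGE_ORDER:
        if name not in report.stages:
            continue
        st = report.stages[name]
        lines.append(f"## {name}")
        if st["status"] != "ok":
            lines.append(f"FAILED: {st.get('error', 'unknown error')}")
        else:
            for k, v in st.get("summary", {}).items():
                if isinstance(v, float):
                    lines.append(f"- {k}: {v:.6g}")
                else:
                    lines.append(f"- {k}: {v}")
        lines.append("")
    return "\n".join(lines)
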