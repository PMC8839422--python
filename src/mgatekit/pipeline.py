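"""Orchestration: configuration → all analyses → report bundle → comparison.

Every analysis a config enables runs over one code path, so the
wild-type and each mutant of a comparison study are just different
configs (or different trajectories under the same config).  The bundle
records a provenance block (config hash, frame window, versions) and
every table carries the window it was computed under; reruns with
identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, MGateError
from .model_io import (
    AnalysisConfig,
    Structure,
    Trajectory,
    read_structure,
    read_trajectory,
)
from .symmetry import SymmetrySeries, TripletMap, psi_series, psi_summary
from .interactions import attachment_scores, build_network, network_graph
from .dynamics import GapEvent, gap_events, min_distance_series, rmsf, solvent_count_series

__all__ = ["ReportBundle", "SystemDelta", "run_pipeline", "compare_systems", "config_hash"]


def _config_dict(config: AnalysisConfig) -> dict:
    return {
        "helix_map": {k: list(v) for k, v in sorted(config.helix_map.segments.items())},
        "helix_names": sorted(config.helix_map.helix_names),
        "domain_map": dict(sorted(config.domain_map.items())),
        "triplet_offsets": {k: list(v) for k, v in sorted(config.triplet_offsets.items())},
        "triplets": list(config.triplets),
        "triplet_atom": config.triplet_atom,
        "psi_mode": config.psi_mode,
        "interactions": [
            {
                "type": s.kind, "a": s.sel_a, "b": s.sel_b,
                "label_a": s.label_a, "label_b": s.label_b,
                "cutoffs": dict(sorted(s.cutoff_overrides.items())),
            }
            for s in config.interactions
        ],
        "frame_window": [config.frame_window.start, config.frame_window.end],
        "stride": config.stride,
        "cutoffs": asdict(config.cutoffs),
        "rmsf_selection": config.rmsf_selection,
        "distance_pairs": [list(p) for p in config.distance_pairs],
        "gap_min_duration": config.gap_min_duration,
        "solvent_groups": list(config.solvent_groups) if config.solvent_groups else None,
        "report_floor": config.report_floor,
    }


def config_hash(config: AnalysisConfig) -> str:
    """Stable SHA-256 digest of the canonical config serialization."""
    canon = json.dumps(_config_dict(config), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All outputs of one analysis run plus provenance."""

    occupancy_table: pd.DataFrame | None = None
    network: dict | None = None
    attachment: dict[tuple[str, str], float] | None = None
    symmetry_series: SymmetrySeries | None = None
    symmetry_summary: pd.DataFrame | None = None
    rmsf_profile: pd.DataFrame | None = None
    distance_series: dict[str, np.ndarray] = field(default_factory=dict)
    gap_event_lists: dict[str, list[GapEvent]] = field(default_factory=dict)
    solvent_counts: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = {"index": False, "float_format": "%.6f", "lineterminator": "\n"}
        if self.occupancy_table is not None:
            self.occupancy_table.to_csv(out / "occupancy_table.csv", **kw)
        if self.network is not None:
            (out / "network.json").write_text(json.dumps(self.network, sort_keys=True))
        if self.attachment is not None:
            payload = {f"{a}-{b}": v for (a, b), v in sorted(self.attachment.items())}
            (out / "attachment_scores.json").write_text(json.dumps(payload, sort_keys=True))
        if self.symmetry_series is not None:
            self.symmetry_series.to_frame().to_csv(out / "psi_series.csv", **kw)
        if self.symmetry_summary is not None:
            self.symmetry_summary.to_csv(out / "psi_summary.csv", **kw)
        if self.rmsf_profile is not None:
            self.rmsf_profile.to_csv(out / "rmsf.csv", **kw)
        for label, series in self.distance_series.items():
            pd.DataFrame({
                "frame": np.arange(len(series)), "distance_angstrom": series,
            }).to_csv(out / f"distance_{label}.csv", **kw)
        for label, events in self.gap_event_lists.items():
            pd.DataFrame([
                {"start_frame": e.start_frame, "end_frame": e.end_frame, "max_gap": e.max_gap}
                for e in events
            ], columns=["start_frame", "end_frame", "max_gap"]).to_csv(
                out / f"gap_events_{label}.csv", **kw)
        if self.solvent_counts is not None:
            pd.DataFrame({
                "frame": np.arange(len(self.solvent_counts)),
                "bridging_solvent_count": self.solvent_counts,
            }).to_csv(out / "solvent_counts.csv", **kw)
        (out / "provenance.json").write_text(json.dumps(self.provenance, sort_keys=True))

    @classmethod
    def load(cls, out_dir: str | Path) -> "ReportBundle":
        """Reload the comparable tables of a written bundle (occupancy,
        ψ summary, RMSF, provenance); per-frame series are not reloaded."""
        out = Path(out_dir)
        bundle = cls()
        if (out / "occupancy_table.csv").exists():
            bundle.occupancy_table = pd.read_csv(out / "occupancy_table.csv")
        if (out / "psi_summary.csv").exists():
            bundle.symmetry_summary = pd.read_csv(out / "psi_summary.csv")
        if (out / "rmsf.csv").exists():
            bundle.rmsf_profile = pd.read_csv(out / "rmsf.csv")
        if (out / "provenance.json").exists():
            bundle.provenance = json.loads((out / "provenance.json").read_text())
        return bundle


def _stage(name: str):
    """Decorator context: re-raise stage failures with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MGateError):
                raise type(exc)(f"stage '{name}': {exc}") from exc
            return False
    return _Ctx()


def run_pipeline(
    config: AnalysisConfig,
    topology: Structure | str | Path,
    trajectory: Trajectory | str | Path,
    out_dir: str | Path | None = None,
    auto_enumerate: bool = False,
) -> ReportBundle:
    """Run every analysis the config enables and (optionally) write the
    report bundle.  Deterministic given identical inputs."""
    if not isinstance(topology, Structure):
        topology = read_structure(topology)
    if not isinstance(trajectory, Trajectory):
        trajectory = read_trajectory(trajectory, topology)

    bundle = ReportBundle()
    i0, i1 = config.frame_window.resolve(trajectory.n_frames)
    bundle.provenance = {
        "config_hash": config_hash(config),
        "mgatekit_version": __version__,
        "n_frames": trajectory.n_frames,
        "frame_window": [i0, i1],
        "stride": config.stride,
    }

    if config.interactions or auto_enumerate:
        with _stage("network"):
            bundle.occupancy_table = build_network(
                trajectory, config, auto_enumerate=auto_enumerate
            )
            import networkx as nx
            graph = network_graph(bundle.occupancy_table, config.helix_map,
                                  config.domain_map)
            bundle.network = nx.node_link_data(graph, edges="links")
        if config.domain_map:
            with _stage("attachment"):
                bundle.attachment = attachment_scores(
                    bundle.occupancy_table, config.helix_map, config.domain_map
                )

    if config.triplets:
        with _stage("psi"):
            if not config.triplet_offsets:
                raise ConfigError("triplets configured without triplet_offsets")
            tmap = TripletMap(offsets=config.triplet_offsets, helix_map=config.helix_map)
            bundle.symmetry_series = psi_series(
                trajectory, tmap, config.triplets,
                atom_name=config.triplet_atom, mode=config.psi_mode,
            )
            bundle.symmetry_summary = psi_summary(bundle.symmetry_series, config.frame_window)

    if config.rmsf_selection:
        with _stage("rmsf"):
            bundle.rmsf_profile = rmsf(
                trajectory, config.rmsf_selection, config.frame_window,
                helix_map=config.helix_map,
            )

    for label, sel_a, sel_b in config.distance_pairs:
        with _stage(f"distance:{label}"):
            series = min_distance_series(trajectory, sel_a, sel_b, config.helix_map)
            bundle.distance_series[label] = series
            bundle.gap_event_lists[label] = gap_events(
                series, config.cutoffs.gap_open, config.gap_min_duration
            )

    if config.solvent_groups is not None:
        with _stage("solvent"):
            bundle.solvent_counts = solvent_count_series(
                trajectory, config.solvent_groups[0], config.solvent_groups[1],
                radius=config.cutoffs.solvent_radius, helix_map=config.helix_map,
            )

    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


@dataclass
class SystemDelta:
    """Differences between two systems (B − A): per-edge occupancy,
    per-triplet mean ψ, per-residue RMSF.  Antisymmetric under swap."""

    occupancy_delta: pd.DataFrame | None = None
    psi_delta: pd.DataFrame | None = None
    rmsf_delta: pd.DataFrame | None = None

    def write(self, path: str | Path) -> None:
        path = Path(path)
        kw = {"index": False, "float_format": "%.6f", "lineterminator": "\n"}
        if self.occupancy_delta is not None:
            self.occupancy_delta.to_csv(path, **kw)
        if self.psi_delta is not None:
            self.psi_delta.to_csv(path.with_name(path.stem + "_psi.csv"), **kw)
        if self.rmsf_delta is not None:
            self.rmsf_delta.to_csv(path.with_name(path.stem + "_rmsf.csv"), **kw)


def compare_systems(report_a: ReportBundle, report_b: ReportBundle) -> SystemDelta:
    """Per-edge, per-triplet and per-residue differences, B − A.

    Edges absent from one system count as 0% occupancy there (a
    destroyed salt bridge shows up as a negative delta, not a missing
    row).  ψ and RMSF comparisons require the same triplets / residues
    in both reports.
    """
    delta = SystemDelta()

    if (report_a.occupancy_table is None) != (report_b.occupancy_table is None):
        raise ConfigError("incompatible reports: only one has an occupancy table")
    if report_a.occupancy_table is not None:
        key = ["res_a", "res_b", "type"]
        a = report_a.occupancy_table.set_index(key)["occupancy_pct"]
        b = report_b.occupancy_table.set_index(key)["occupancy_pct"]
        if a.index.has_duplicates or b.index.has_duplicates:
            raise ConfigError("duplicate interaction rows; cannot align edges")
        idx = a.index.union(b.index)
        diff = b.reindex(idx, fill_value=0.0) - a.reindex(idx, fill_value=0.0)
        delta.occupancy_delta = diff.rename("delta_occupancy_pct").reset_index()

    if (report_a.symmetry_summary is None) != (report_b.symmetry_summary is None):
        raise ConfigError("incompatible reports: only one has a ψ summary")
    if report_a.symmetry_summary is not None:
        a = report_a.symmetry_summary.set_index("triplet")["mean_psi_deg"]
        b = report_b.symmetry_summary.set_index("triplet")["mean_psi_deg"]
        if not a.index.equals(b.index):
            raise ConfigError("incompatible reports: different triplet sets")
        delta.psi_delta = (b - a).rename("delta_mean_psi_deg").reset_index()

    if (report_a.rmsf_profile is None) != (report_b.rmsf_profile is None):
        raise ConfigError("incompatible reports: only one has an RMSF profile")
    if report_a.rmsf_profile is not None:
        key = ["residue", "atom"]
        a = report_a.rmsf_profile.set_index(key)["rmsf_angstrom"]
        b = report_b.rmsf_profile.set_index(key)["rmsf_angstrom"]
        if not a.index.equals(b.index):
            raise ConfigError("incompatible reports: different RMSF atom sets")
        delta.rmsf_delta = (b - a).rename("delta_rmsf_angstrom").reset_index()

    return delta
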