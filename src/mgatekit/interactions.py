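"""Per-frame interaction detection and occupancy networks.

Detects salt bridges, hydrogen bonds, guanidinium stacking and
ligand contacts frame by frame, turns presence into percent occupancy
over an analysis window, classifies each edge as intra-helical,
inter-helical or other, and aggregates inter-domain attachment scores.

Geometric criteria (all configurable):

* salt bridge — minimum side-chain N···O distance ≤ 4.0 Å (boundary
  counts as formed); charged sites are NH1/NH2/NE (Arg), NZ (Lys),
  OD1/OD2 (Asp), OE1/OE2 (Glu), or a dedicated charge-site pseudo-atom
  on coarse models;
* H-bond — donor–acceptor heavy-atom distance ≤ 3.5 Å and, when an
  explicit hydrogen exists, H–donor–acceptor angle ≤ 30°; topologies
  without hydrogens (crystal structures, toy models) fall back to the
  distance criterion alone;
* guanidinium stacking — plane centroid distance ≤ 5.0 Å and
  interplanar angle (folded into [0°, 90°]) ≤ 30°;
* ligand contact — an H-bond/salt-bridge style minimum-distance
  criterion whose partner B is typically a HETATM selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, SelectionError
from .model_io import (
    AnalysisConfig,
    AtomGroup,
    FrameWindow,
    HelixMap,
    Structure,
    Trajectory,
    select_atoms,
)

__all__ = [
    "InteractionSpec",
    "OccupancySeries",
    "detect_salt_bridge",
    "detect_hbond",
    "detect_stacking",
    "occupancy",
    "classify_interaction",
    "build_network",
    "attachment_scores",
    "round_half_away",
]

BASIC_SITE_ATOMS = {"NH1", "NH2", "NE", "NZ"}
ACIDIC_SITE_ATOMS = {"OD1", "OD2", "OE1", "OE2"}
PSEUDO_SITE_ATOMS = {"CS"}  # charge-site pseudo-atom on coarse/toy models
CHARGED_SITE_ATOMS = BASIC_SITE_ATOMS | ACIDIC_SITE_ATOMS | PSEUDO_SITE_ATOMS
GUANIDINIUM_ATOMS = ("CZ", "NH1", "NH2", "NE")

INTRA = "intra_helical"
INTER = "inter_helical"
OTHER = "other"


@dataclass
class InteractionSpec:
    """One candidate interaction: a type, two partner selections and
    optional per-spec cutoff overrides."""

    kind: str
    sel_a: str
    sel_b: str
    label_a: str = ""
    label_b: str = ""
    cutoff_overrides: dict[str, float] = field(default_factory=dict)

    KINDS = ("salt_bridge", "hbond", "stacking", "ligand_contact")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ConfigError(f"interaction type '{self.kind}' not in {self.KINDS}")
        if not self.label_a:
            self.label_a = self.sel_a
        if not self.label_b:
            self.label_b = self.sel_b


@dataclass
class OccupancySeries:
    """Per-frame presence and minimum distance for one interaction."""

    spec: InteractionSpec
    present: np.ndarray
    min_distance: np.ndarray

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        self.min_distance = np.asarray(self.min_distance, dtype=float)
        if self.present.shape != self.min_distance.shape:
            raise DataError("occupancy series length mismatch")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (occupancies are reported this way)."""
    factor = 10 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


# ---------------------------------------------------------------------------
# Site resolution
# ---------------------------------------------------------------------------

def _residue_site_indices(structure: Structure, resnum: int, role: str) -> np.ndarray:
    """Indices of the charged-site atoms of one residue.

    ``role`` is "basic" or "acidic".  Canonical side-chain atoms are
    preferred; a charge-site pseudo-atom ("CS") is accepted in their
    absence, which is how coarse toy models carry their charges.
    """
    mask = structure.res_numbers == resnum
    if not mask.any():
        raise DataError(f"no residue numbered {resnum} in structure")
    names = structure.atom_names[mask]
    wanted = BASIC_SITE_ATOMS if role == "basic" else ACIDIC_SITE_ATOMS
    idx = np.flatnonzero(mask)
    canonical = idx[np.isin(names.astype(str), list(wanted))]
    if len(canonical):
        return canonical
    pseudo = idx[np.isin(names.astype(str), list(PSEUDO_SITE_ATOMS))]
    if len(pseudo):
        return pseudo
    raise DataError(
        f"residue {resnum}: neither canonical {sorted(wanted)} atoms nor a "
        f"charge-site pseudo-atom found"
    )


def _narrow_to_sites(group: AtomGroup) -> np.ndarray:
    """Restrict a selection to charged-site atoms when it contains any;
    explicit atom-level selections pass through unchanged."""
    s = group.structure
    names = s.atom_names[group.indices].astype(str)
    mask = np.isin(names, list(CHARGED_SITE_ATOMS))
    if mask.any():
        return group.indices[mask]
    return group.indices


def _min_cross_distance(frame: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    d = np.linalg.norm(frame[idx_a][:, None, :] - frame[idx_b][None, :, :], axis=-1)
    return float(d.min())


# ---------------------------------------------------------------------------
# Per-frame detectors
# ---------------------------------------------------------------------------

def detect_salt_bridge(
    structure: Structure,
    frame: np.ndarray,
    res_basic: int,
    res_acidic: int,
    cutoff: float = 4.0,
) -> tuple[bool, float]:
    """Salt bridge between a basic and an acidic residue in one frame.

    Formed iff the minimum over all basic-N × acidic-O (or pseudo-site)
    atom pairs is ≤ cutoff; a distance exactly at the cutoff counts as
    formed.
    """
    idx_n = _residue_site_indices(structure, res_basic, "basic")
    idx_o = _residue_site_indices(structure, res_acidic, "acidic")
    dmin = _min_cross_distance(np.asarray(frame, dtype=float), idx_n, idx_o)
    return dmin <= cutoff, dmin


def detect_hbond(
    structure: Structure,
    frame: np.ndarray,
    donor_sel: str,
    acceptor_sel: str,
    d_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
    hydrogen_sel: str | None = None,
    helix_map: HelixMap | None = None,
) -> bool:
    """Hydrogen bond between a donor heavy atom and an acceptor.

    Distance criterion on the donor–acceptor heavy-atom pair; when a
    hydrogen selection is given the H–donor–acceptor angle must also be
    within ``angle_cutoff``.  Hydrogen-free topologies use the distance
    criterion alone.
    """
    frame = np.asarray(frame, dtype=float)
    donors = select_atoms(structure, donor_sel, helix_map)
    acceptors = select_atoms(structure, acceptor_sel, helix_map)
    if len(donors) == 0 or len(acceptors) == 0:
        raise SelectionError("H-bond donor/acceptor selection resolves to no atoms")
    d = np.linalg.norm(
        frame[donors.indices][:, None, :] - frame[acceptors.indices][None, :, :], axis=-1
    )
    if hydrogen_sel is None:
        return bool(d.min() <= d_cutoff)
    hydrogens = select_atoms(structure, hydrogen_sel, helix_map)
    if len(hydrogens) == 0:
        raise SelectionError("hydrogen selection resolves to no atoms")
    for i, di in enumerate(donors.indices):
        for j, aj in enumerate(acceptors.indices):
            if d[i, j] > d_cutoff:
                continue
            for h in hydrogens.indices:
                v_dh = frame[h] - frame[di]
                v_da = frame[aj] - frame[di]
                nh, na = np.linalg.norm(v_dh), np.linalg.norm(v_da)
                if nh < 1e-9 or na < 1e-9:
                    continue
                ang = np.degrees(np.arccos(np.clip(v_dh @ v_da / (nh * na), -1, 1)))
                if ang <= angle_cutoff:
                    return True
    return False


def _guanidinium_plane(structure: Structure, frame: np.ndarray, resnum: int):
    res = structure.residue(resnum)
    if str(res.name) != "ARG":
        raise DataError(f"residue {resnum} ({res.name}) is not ARG; stacking needs a guanidinium group")
    try:
        idx = [structure.atom_index(resnum, n) for n in GUANIDINIUM_ATOMS]
    except DataError as exc:
        raise DataError(f"residue {resnum}: missing guanidinium plane atom ({exc})") from exc
    pts = frame[idx]
    centroid = pts.mean(axis=0)
    # plane normal from the two in-plane CZ->NH vectors
    normal = np.cross(pts[1] - pts[0], pts[2] - pts[0])
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise DataError(f"residue {resnum}: degenerate guanidinium plane")
    return centroid, normal / nn


def detect_stacking(
    structure: Structure,
    frame: np.ndarray,
    res_i: int,
    res_j: int,
    d_cutoff: float = 5.0,
    angle_cutoff: float = 30.0,
) -> bool:
    """Arg–Arg guanidinium stacking: near-parallel planes with close
    centroids.  The interplanar angle is folded into [0°, 90°]."""
    frame = np.asarray(frame, dtype=float)
    ci, ni = _guanidinium_plane(structure, frame, res_i)
    cj, nj = _guanidinium_plane(structure, frame, res_j)
    if np.linalg.norm(ci - cj) > d_cutoff:
        return False
    ang = np.degrees(np.arccos(np.clip(abs(ni @ nj), -1, 1)))
    return bool(ang <= angle_cutoff)


# ---------------------------------------------------------------------------
# Occupancy over a window
# ---------------------------------------------------------------------------

def _resolve_spec_indices(
    topology: Structure, spec: InteractionSpec, helix_map: HelixMap | None
) -> tuple[np.ndarray, np.ndarray]:
    ga = select_atoms(topology, spec.sel_a, helix_map)
    gb = select_atoms(topology, spec.sel_b, helix_map)
    if len(ga) == 0 or len(gb) == 0:
        raise SelectionError(
            f"interaction {spec.label_a}:{spec.label_b}: empty partner selection"
        )
    if spec.kind in ("salt_bridge", "hbond", "ligand_contact"):
        return _narrow_to_sites(ga), _narrow_to_sites(gb)
    return ga.indices, gb.indices


def _spec_cutoff(spec: InteractionSpec, cutoffs) -> float:
    if spec.kind == "salt_bridge":
        return spec.cutoff_overrides.get("distance", cutoffs.salt_bridge)
    if spec.kind == "hbond":
        return spec.cutoff_overrides.get("distance", cutoffs.hbond_distance)
    if spec.kind == "ligand_contact":
        return spec.cutoff_overrides.get("distance", cutoffs.salt_bridge)
    return spec.cutoff_overrides.get("distance", cutoffs.stacking_distance)


def _stacking_series(
    trajectory: Trajectory, spec: InteractionSpec, cutoffs, helix_map
) -> tuple[np.ndarray, np.ndarray]:
    top = trajectory.topology
    ra = _unique_resnum(top, spec.sel_a, helix_map)
    rb = _unique_resnum(top, spec.sel_b, helix_map)
    if ra is None or rb is None:
        raise ConfigError("stacking spec must select exactly one residue per side")
    idx_a = [top.atom_index(ra, n) for n in GUANIDINIUM_ATOMS]
    idx_b = [top.atom_index(rb, n) for n in GUANIDINIUM_ATOMS]
    pa = trajectory.coords[:, idx_a, :]
    pb = trajectory.coords[:, idx_b, :]
    ca, cb = pa.mean(axis=1), pb.mean(axis=1)
    na = np.cross(pa[:, 1] - pa[:, 0], pa[:, 2] - pa[:, 0])
    nb = np.cross(pb[:, 1] - pb[:, 0], pb[:, 2] - pb[:, 0])
    na /= np.linalg.norm(na, axis=-1, keepdims=True)
    nb /= np.linalg.norm(nb, axis=-1, keepdims=True)
    dist = np.linalg.norm(ca - cb, axis=-1)
    ang = np.degrees(np.arccos(np.clip(np.abs(np.sum(na * nb, axis=-1)), -1, 1)))
    d_cut = _spec_cutoff(spec, cutoffs)
    a_cut = spec.cutoff_overrides.get("angle", cutoffs.stacking_angle)
    return (dist <= d_cut) & (ang <= a_cut), dist


def occupancy(
    trajectory: Trajectory,
    spec: InteractionSpec,
    frame_window: FrameWindow | None = None,
    cutoffs=None,
    helix_map: HelixMap | None = None,
    stride: int = 1,
) -> tuple[float, OccupancySeries]:
    """Percent of window frames in which the interaction is present.

    The full per-frame series (presence and minimum distance) is
    returned alongside the percentage for plotting and event analysis;
    the percentage itself is computed on the window frames only,
    optionally sub-strided.
    """
    from .model_io import Cutoffs
    cutoffs = cutoffs or Cutoffs()
    if spec.kind == "stacking":
        present, dmin = _stacking_series(trajectory, spec, cutoffs, helix_map)
    else:
        idx_a, idx_b = _resolve_spec_indices(trajectory.topology, spec, helix_map)
        diffs = trajectory.coords[:, idx_a, None, :] - trajectory.coords[:, None, idx_b, :]
        dmin = np.linalg.norm(diffs, axis=-1).min(axis=(1, 2))
        present = dmin <= _spec_cutoff(spec, cutoffs)
    series = OccupancySeries(spec=spec, present=present, min_distance=dmin)
    n = trajectory.n_frames
    i0, i1 = (frame_window or FrameWindow(0, n)).resolve(n)
    window = present[i0:i1:stride]
    if window.size == 0:
        raise ConfigError("empty frame window for occupancy")
    return 100.0 * float(window.sum()) / window.size, series


# ---------------------------------------------------------------------------
# Classification and network assembly
# ---------------------------------------------------------------------------

def classify_interaction(res_i: int, res_j: int, helix_map: HelixMap) -> str:
    """intra_helical (same helix), inter_helical (two different helices)
    or other (either partner on a loop/matrix-helix segment).
    Symmetric in its arguments."""
    seg_i = helix_map.segment_of(res_i)
    seg_j = helix_map.segment_of(res_j)
    if helix_map.is_helix(seg_i) and helix_map.is_helix(seg_j):
        return INTRA if seg_i == seg_j else INTER
    return OTHER


def _unique_resnum(topology: Structure, sel: str, helix_map) -> int | None:
    group = select_atoms(topology, sel, helix_map)
    nums = set(topology.res_numbers[group.indices].tolist())
    return nums.pop() if len(nums) == 1 else None


def _auto_enumerate_pairs(
    topology: Structure, seed_distance: float, helix_map
) -> list[InteractionSpec]:
    """All basic×acidic residue pairs whose charged sites come within the
    seed distance on the reference coordinates."""
    basic_res = sorted(set(
        topology.res_numbers[np.isin(topology.res_names.astype(str), ["ARG", "LYS", "HIS"])]
    ))
    acidic_res = sorted(set(
        topology.res_numbers[np.isin(topology.res_names.astype(str), ["ASP", "GLU"])]
    ))
    specs = []
    for rb in basic_res:
        try:
            idx_n = _residue_site_indices(topology, rb, "basic")
        except DataError:
            continue
        for ra in acidic_res:
            if ra == rb:
                continue
            try:
                idx_o = _residue_site_indices(topology, ra, "acidic")
            except DataError:
                continue
            if _min_cross_distance(topology.coords, idx_n, idx_o) <= seed_distance:
                specs.append(InteractionSpec(
                    kind="salt_bridge",
                    sel_a=f"resid {rb}",
                    sel_b=f"resid {ra}",
                    label_a=str(rb),
                    label_b=str(ra),
                ))
    return specs


def build_network(
    trajectory: Trajectory,
    config: AnalysisConfig,
    auto_enumerate: bool = False,
    seed_distance: float = 8.0,
) -> pd.DataFrame:
    """Occupancy table over all candidate interactions.

    One row per candidate: partner labels, type, intra/inter class,
    occupancy %, window size and a below-floor flag.  Rows under the
    reporting floor (default 5%) are flagged but kept, so comparisons
    between systems never lose edges.
    """
    specs = list(config.interactions)
    if auto_enumerate:
        specs += _auto_enumerate_pairs(trajectory.topology, seed_distance, config.helix_map)
    if not specs:
        raise ConfigError("no interactions configured and auto-enumeration not requested")
    i0, i1 = config.frame_window.resolve(trajectory.n_frames)
    n_window = len(range(i0, i1, config.stride))
    rows = []
    for spec in specs:
        pct, _series = occupancy(
            trajectory, spec, config.frame_window, config.cutoffs,
            config.helix_map, config.stride,
        )
        ra = _unique_resnum(trajectory.topology, spec.sel_a, config.helix_map)
        rb = _unique_resnum(trajectory.topology, spec.sel_b, config.helix_map)
        cls = classify_interaction(ra, rb, config.helix_map) if ra and rb else OTHER
        rows.append({
            "res_a": spec.label_a,
            "res_b": spec.label_b,
            "resnum_a": ra,
            "resnum_b": rb,
            "type": spec.kind,
            "class": cls,
            "occupancy_pct": round_half_away(pct, 1),
            "below_floor": pct < config.report_floor,
            "n_frames_window": n_window,
        })
    return pd.DataFrame(rows)


def combine_occupancies(tables: list[pd.DataFrame], mode: str = "mean") -> pd.DataFrame:
    """Combine occupancy tables from replicate trajectories of one system.

    ``mean`` averages the per-trajectory occupancy percentages edge by
    edge; ``pool`` weights each trajectory by its window frame count,
    equivalent to pooling all window frames before computing occupancy.
    Every table must list the same edges.
    """
    if not tables:
        raise ConfigError("no occupancy tables to combine")
    if mode not in ("mean", "pool"):
        raise ConfigError(f"unknown combination mode '{mode}'")
    key = ["res_a", "res_b", "type"]
    ref = tables[0].set_index(key).sort_index()
    combined = ref.copy()
    pcts = np.zeros(len(ref))
    weights = 0.0
    for t in tables:
        t = t.set_index(key).sort_index()
        if not t.index.equals(ref.index):
            raise ConfigError("occupancy tables list different edges; cannot combine")
        w = float(t["n_frames_window"].iloc[0]) if mode == "pool" else 1.0
        pcts += w * t["occupancy_pct"].to_numpy()
        weights += w
    combined["occupancy_pct"] = pcts / weights
    combined["n_frames_window"] = sum(int(t["n_frames_window"].iloc[0]) for t in tables)
    combined["below_floor"] = combined["occupancy_pct"] < 5.0
    return combined.reset_index()


def network_graph(
    table: pd.DataFrame,
    helix_map: HelixMap,
    domain_map: dict[str, str] | None = None,
):
    """Occupancy table as a networkx graph (nodes: residues annotated
    with segment/domain; edges: occupancy %, type, class)."""
    import networkx as nx

    g = nx.Graph()
    domain_map = domain_map or {}
    for _, row in table.iterrows():
        for label, num in ((row["res_a"], row["resnum_a"]), (row["res_b"], row["resnum_b"])):
            if label in g:
                continue
            seg = helix_map.segment_of(int(num)) if num is not None and not pd.isna(num) else None
            g.add_node(label, residue=None if num is None or pd.isna(num) else int(num),
                       segment=seg, domain=domain_map.get(seg))
        g.add_edge(row["res_a"], row["res_b"], type=row["type"],
                   interaction_class=row["class"],
                   occupancy_pct=float(row["occupancy_pct"]),
                   below_floor=bool(row["below_floor"]))
    return g


def attachment_scores(
    table: pd.DataFrame,
    helix_map: HelixMap,
    domain_map: dict[str, str],
) -> dict[tuple[str, str], float]:
    """Inter-domain attachment: for each domain pair, the sum of
    occupancy % over inter-helical edges bridging the two domains.

    Quantifies how strongly two domains hold on to each other through
    their helix–helix contacts (e.g. domains 2–3 binding tightly while
    domain 1 attaches loosely)."""
    domains = sorted(set(domain_map.values()))
    scores: dict[tuple[str, str], float] = {
        (a, b): 0.0 for i, a in enumerate(domains) for b in domains[i + 1:]
    }
    for _, row in table.iterrows():
        if row["class"] != INTER or row["resnum_a"] is None or row["resnum_b"] is None:
            continue
        seg_a = helix_map.segment_of(int(row["resnum_a"]))
        seg_b = helix_map.segment_of(int(row["resnum_b"]))
        da, db = domain_map.get(seg_a), domain_map.get(seg_b)
        if da is None or db is None or da == db:
            continue
        key = tuple(sorted((da, db)))
        scores[key] += float(row["occupancy_pct"])
    return scores
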