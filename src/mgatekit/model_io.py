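"""Structures, trajectories, atom selection and analysis configuration.

Coordinates are in Angstrom throughout.  Residue numbering is 1-based
(PDB convention), frame indices are 0-based, times are in ps.  The
normative trajectory exchange format is multi-model PDB (MODEL/ENDMDL);
parsing and writing go through biotite so field conventions (8.3f
coordinates, altloc handling) follow the standard.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigError, DataError, SelectionError

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "AtomGroup",
    "HelixMap",
    "FrameWindow",
    "Cutoffs",
    "AnalysisConfig",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select_atoms",
    "load_config",
]


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single atom: serial number, PDB atom name, element, Å coordinates."""

    serial: int
    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise DataError(f"atom {self.serial} ({self.name}): coordinates must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


@dataclass
class Residue:
    """A residue: 1-based number, 3-letter name, chain id and its atoms."""

    number: int
    name: str
    chain: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise DataError(f"residue {self.chain}:{self.number} has duplicate atom names")

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise DataError(f"residue {self.chain}:{self.number} ({self.name}) has no atom '{name}'")


class Structure:
    """An ordered collection of residues with flat per-atom array views.

    The flat arrays (``coords``, ``atom_names``, ``res_numbers`` ...) are
    what the analysis modules operate on; the residue list is the
    user-facing construction interface.
    """

    def __init__(self, residues: Sequence[Residue], title: str = ""):
        if not residues:
            raise DataError("structure must contain at least one residue")
        keys = [(r.chain, r.number) for r in residues]
        if len(set(keys)) != len(keys):
            raise DataError("duplicate (chain, residue number) in structure")
        self.residues: list[Residue] = list(residues)
        self.title = title
        self._build_arrays()

    def _build_arrays(self) -> None:
        coords, anames, elements, rnum, rname, chains, serials = [], [], [], [], [], [], []
        for r in self.residues:
            for a in r.atoms:
                coords.append(a.coords)
                anames.append(a.name)
                elements.append(a.element)
                rnum.append(r.number)
                rname.append(r.name)
                chains.append(r.chain)
                serials.append(a.serial)
        if not coords:
            raise DataError("structure contains zero atoms")
        self.coords = np.array(coords, dtype=float)
        self.atom_names = np.array(anames, dtype=object)
        self.elements = np.array(elements, dtype=object)
        self.res_numbers = np.array(rnum, dtype=int)
        self.res_names = np.array(rname, dtype=object)
        self.chains = np.array(chains, dtype=object)
        self.serials = np.array(serials, dtype=int)
        self._index = {
            (c, n, a): i
            for i, (c, n, a) in enumerate(zip(chains, rnum, anames))
        }
        self._index_nochain: dict[tuple[int, str], list[int]] = {}
        for i, (n, a) in enumerate(zip(rnum, anames)):
            self._index_nochain.setdefault((n, a), []).append(i)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def atom_index(self, resnum: int, atom_name: str, chain: str | None = None) -> int:
        """Flat index of one atom; raises if absent (lookup is total or fails)."""
        if chain is None:
            hits = self._index_nochain.get((resnum, atom_name), [])
            if len(hits) == 1:
                return hits[0]
            if len(hits) > 1:
                raise SelectionError(
                    f"atom {atom_name} of residue {resnum} is ambiguous across chains; "
                    f"specify the chain"
                )
            raise DataError(f"no atom {atom_name} in residue {resnum}")
        key = (chain, resnum, atom_name)
        if key not in self._index:
            raise DataError(f"no atom {atom_name} in residue {chain}:{resnum}")
        return self._index[key]

    def residue(self, resnum: int, chain: str | None = None) -> Residue:
        for r in self.residues:
            if r.number == resnum and (chain is None or r.chain == chain):
                return r
        raise DataError(f"no residue numbered {resnum}" + (f" in chain {chain}" if chain else ""))

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A copy of this structure with replaced coordinates (same topology)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise DataError("replacement coordinates have wrong shape")
        residues = []
        i = 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(Atom(a.serial, a.name, a.element, coords[i]))
                i += 1
            residues.append(Residue(r.number, r.name, r.chain, atoms))
        return Structure(residues, title=self.title)


@dataclass
class Trajectory:
    """Frames sharing one topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å.  ``frame_times``
    (ps) is optional and must be strictly increasing when present.
    """

    topology: Structure
    coords: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise DataError("trajectory coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise DataError(
                f"frame atom count {self.coords.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}"
            )
        if self.coords.shape[0] == 0:
            raise DataError("empty trajectory")
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != self.n_frames:
                raise DataError("frame_times length != frame count")
            if np.any(np.diff(t) <= 0):
                raise DataError("frame_times must be strictly increasing")
            self.frame_times = t

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]


@dataclass(frozen=True)
class AtomGroup:
    """Ordered, unique atom indices into a Structure (topology order)."""

    structure: Structure
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise SelectionError("atom indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise SelectionError("atom indices must be unique")
        if len(idx) and (idx.min() < 0 or idx.max() >= self.structure.n_atoms):
            raise SelectionError("atom index out of range")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords[self.indices]


# ---------------------------------------------------------------------------
# Segment map
# ---------------------------------------------------------------------------

@dataclass
class HelixMap:
    """Assignment of residue-number ranges to named segments.

    ``segments`` maps a segment name (``"H1"``, ``"h12"``, ``"C1"`` ...)
    to an inclusive residue range.  Segment names listed in
    ``helix_names`` count as transmembrane helices for intra-/inter-
    helical classification; by default every name matching ``H`` +
    digits.  Residues not covered by any segment belong to
    ``default_segment`` (``"loop"``) unless that is set to None, in
    which case lookups outside the map raise.
    """

    segments: dict[str, tuple[int, int]]
    helix_names: frozenset[str] | None = None
    default_segment: str | None = "loop"

    def __post_init__(self) -> None:
        ranges = []
        for name, rng in self.segments.items():
            lo, hi = int(rng[0]), int(rng[1])
            if lo > hi:
                raise ConfigError(f"helix_map.{name}: range {lo}-{hi} is inverted")
            self.segments[name] = (lo, hi)
            ranges.append((lo, hi, name))
        ranges.sort()
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(ranges, ranges[1:]):
            if lo2 <= hi1:
                raise ConfigError(f"helix_map: segments {n1} and {n2} overlap")
        if self.helix_names is None:
            self.helix_names = frozenset(
                n for n in self.segments
                if n.startswith("H") and n[1:].isdigit()
            )
        else:
            self.helix_names = frozenset(self.helix_names)

    def segment_of(self, resnum: int) -> str:
        for name, (lo, hi) in self.segments.items():
            if lo <= resnum <= hi:
                return name
        if self.default_segment is not None:
            return self.default_segment
        raise ConfigError(f"residue {resnum} not covered by any segment")

    def is_helix(self, segment: str) -> bool:
        return segment in self.helix_names

    def residues_of(self, segment: str) -> range:
        if segment not in self.segments:
            raise SelectionError(f"unknown segment '{segment}'")
        lo, hi = self.segments[segment]
        return range(lo, hi + 1)


# ---------------------------------------------------------------------------
# Frame windows and cutoffs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameWindow:
    """Analysis window over trajectory frames.

    ``start``/``end`` are frame indices when int, fractions of the
    trajectory when float in [0, 1].  The default discards the first 20%
    of frames, the usual equilibration discard for occupancy and RMSF
    analyses.
    """

    start: float | int = 0.2
    end: float | int = 1.0

    def resolve(self, n_frames: int) -> tuple[int, int]:
        """Return (first, stop) as a half-open 0-based frame range."""
        def _res(v, default):
            if isinstance(v, bool):
                raise ConfigError("frame_window: boolean is not a frame bound")
            if isinstance(v, float):
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"frame_window: fraction {v} outside [0, 1]")
                return int(round(v * n_frames))
            return int(v)

        i0 = _res(self.start, 0)
        i1 = _res(self.end, n_frames)
        if i0 < 0 or i1 > n_frames or i0 >= i1:
            raise ConfigError(
                f"frame_window [{i0}, {i1}) empty or outside trajectory of {n_frames} frames"
            )
        return i0, i1


@dataclass
class Cutoffs:
    """Geometric interaction criteria (Å, degrees). All must be positive."""

    salt_bridge: float = 4.0
    hbond_distance: float = 3.5
    hbond_angle: float = 30.0
    stacking_distance: float = 5.0
    stacking_angle: float = 30.0
    gap_open: float = 6.0
    solvent_radius: float = 4.0

    def __post_init__(self) -> None:
        for f in (
            "salt_bridge", "hbond_distance", "hbond_angle",
            "stacking_distance", "stacking_angle", "gap_open", "solvent_radius",
        ):
            if getattr(self, f) <= 0:
                raise ConfigError(f"cutoffs.{f}: must be > 0")


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs: segments, triplets, interactions,
    cutoffs and the frame window.  One config per simulated system keeps
    wild-type-vs-mutant comparisons on a single code path."""

    helix_map: HelixMap
    domain_map: dict[str, str] = field(default_factory=dict)
    triplet_offsets: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    triplets: list[int] = field(default_factory=list)
    triplet_atom: str = "CA"
    psi_mode: str = "mean_abs"
    interactions: list = field(default_factory=list)
    frame_window: FrameWindow = field(default_factory=FrameWindow)
    stride: int = 1
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    rmsf_selection: str = "name CA"
    distance_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    gap_min_duration: int = 10
    solvent_groups: tuple[str, str] | None = None
    report_floor: float = 5.0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.psi_mode not in ("mean_abs", "rms"):
            raise ConfigError(f"psi_mode: '{self.psi_mode}' not in ('mean_abs', 'rms')")
        if self.stride < 1:
            raise ConfigError("stride: must be >= 1")
        if self.gap_min_duration < 1:
            raise ConfigError("gap_min_duration: must be >= 1")


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _structure_from_atom_array(arr: bst.AtomArray, title: str = "") -> Structure:
    if arr.array_length() == 0:
        raise DataError("zero atoms in file")
    if hasattr(arr, "ins_code") and np.any(arr.ins_code != ""):
        raise DataError("insertion codes are not supported; renumber the structure")
    residues: list[Residue] = []
    serial = 0
    cur_key = None
    cur_atoms: list[Atom] = []

    def _flush(key):
        if key is not None:
            chain, num, rname = key
            residues.append(Residue(int(num), str(rname), str(chain), cur_atoms.copy()))

    for i in range(arr.array_length()):
        key = (arr.chain_id[i], arr.res_id[i], arr.res_name[i])
        if key != cur_key:
            _flush(cur_key)
            cur_key = key
            cur_atoms.clear()
        serial += 1
        elem = str(arr.element[i]) if str(arr.element[i]).strip() else _guess_element(str(arr.atom_name[i]))
        cur_atoms.append(Atom(serial, str(arr.atom_name[i]), elem, np.asarray(arr.coord[i], dtype=float)))
    _flush(cur_key)
    return Structure(residues, title=title)


def _atom_array_from_structure(structure: Structure, coords: np.ndarray | None = None) -> bst.AtomArray:
    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else structure.coords, dtype=np.float32)
    arr.chain_id = np.array([str(c) for c in structure.chains], dtype="U4")
    arr.res_id = structure.res_numbers.copy()
    arr.res_name = np.array([str(r) for r in structure.res_names], dtype="U5")
    arr.atom_name = np.array([str(a) for a in structure.atom_names], dtype="U6")
    arr.element = np.array([str(e) for e in structure.elements], dtype="U2")
    arr.hetero = np.array(
        [str(r) in ("SOL", "HOH", "WAT") for r in structure.res_names], dtype=bool
    )
    return arr


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a single-model structure (ATOM + HETATM) from a PDB file.

    Highest-occupancy altloc conformers are kept; insertion codes are
    rejected so that residue numbering stays unambiguous.
    """
    path = Path(path)
    if format != "pdb":
        raise DataError(f"unsupported structure format '{format}'")
    if not path.exists():
        raise DataError(f"no such file: {path}")
    with open(path) as fh:
        if not any(line[:6] in ("ATOM  ", "HETATM") for line in fh):
            raise DataError(f"{path}: zero atoms (no ATOM/HETATM records)")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise DataError(f"{path}: malformed PDB ({exc})") from exc
    return _structure_from_atom_array(arr, title=path.stem)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_structure(structure))
    pdb.write(str(Path(path)))


def _scan_model_atom_counts(path: Path) -> list[int]:
    counts, current, in_model = [], 0, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                in_model, current = True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM") and in_model:
                current += 1
    return counts


def read_trajectory(
    path: str | Path,
    topology: Structure,
    frame_times: np.ndarray | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory over the given topology.

    Every MODEL must carry exactly the topology's atom count, in the
    topology's atom order; a mismatching model is reported by its
    1-based frame number.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    counts = _scan_model_atom_counts(path)
    if not counts:
        raise DataError(f"{path}: no MODEL records — empty trajectory")
    for i, c in enumerate(counts, start=1):
        if c != topology.n_atoms:
            raise DataError(
                f"{path}: frame {i} has {c} atoms, topology has {topology.n_atoms}"
            )
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(altloc="first")
    except Exception as exc:
        raise DataError(f"{path}: malformed multi-model PDB ({exc})") from exc
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    return Trajectory(topology=topology, coords=coords, frame_times=frame_times)


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    template = _atom_array_from_structure(trajectory.topology)
    stack = bst.AtomArrayStack(trajectory.n_frames, trajectory.n_atoms)
    stack.coord = trajectory.coords.astype(np.float32)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(Path(path)))


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

_KEYWORDS = {"resid", "resname", "name", "segment", "chain", "element",
             "and", "or", "not", "all", "(", ")"}


def _tokenize(selection: str) -> list[str]:
    out: list[str] = []
    for raw in selection.replace("(", " ( ").replace(")", " ) ").split():
        out.append(raw)
    return out


class _SelParser:
    """Recursive-descent parser for the selection mini-language.

    Grammar::

        expr      := term ("or" term)*
        term      := factor ("and" factor)*
        factor    := "not" factor | "(" expr ")" | primitive
        primitive := "all"
                   | "resid"   (INT | INT:INT)+
                   | "resname" NAME+
                   | "name"    NAME+
                   | "segment" NAME+     (needs a HelixMap)
                   | "chain"   NAME+
                   | "element" NAME+
    """

    def __init__(self, structure: Structure, tokens: list[str], helix_map: HelixMap | None):
        self.s = structure
        self.toks = tokens
        self.pos = 0
        self.helix_map = helix_map

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.pos != len(self.toks):
            raise SelectionError(f"unexpected token '{self.peek()}'")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("missing ')'")
            return mask
        return self.primitive()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword expects at least one value")
        return vals

    def primitive(self) -> np.ndarray:
        tok = self.take()
        n = self.s.n_atoms
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "resid":
            mask = np.zeros(n, dtype=bool)
            for v in self._values():
                if ":" in v:
                    lo_s, hi_s = v.split(":", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionError(f"bad residue range '{v}'") from None
                    mask |= (self.s.res_numbers >= lo) & (self.s.res_numbers <= hi)
                else:
                    try:
                        mask |= self.s.res_numbers == int(v)
                    except ValueError:
                        raise SelectionError(f"bad residue number '{v}'") from None
            return mask
        if tok == "resname":
            vals = set(self._values())
            return np.isin(self.s.res_names.astype(str), list(vals))
        if tok == "name":
            vals = set(self._values())
            return np.isin(self.s.atom_names.astype(str), list(vals))
        if tok == "chain":
            vals = set(self._values())
            return np.isin(self.s.chains.astype(str), list(vals))
        if tok == "element":
            vals = {v.upper() for v in self._values()}
            return np.isin(np.char.upper(self.s.elements.astype(str)), list(vals))
        if tok == "segment":
            if self.helix_map is None:
                raise SelectionError("segment selection requires a helix map")
            mask = np.zeros(n, dtype=bool)
            for v in self._values():
                rng = self.helix_map.residues_of(v)  # raises on unknown segment
                mask |= (self.s.res_numbers >= rng.start) & (self.s.res_numbers < rng.stop)
            return mask
        raise SelectionError(f"unknown selection keyword '{tok}'")


def select_atoms(
    structure: Structure,
    selection: str,
    helix_map: HelixMap | None = None,
) -> AtomGroup:
    """Evaluate a selection expression; result is in topology order.

    An empty result is legal (some analyses treat it as "nothing to do")
    but the group knows it is empty so callers can flag it.
    """
    if not selection or not selection.strip():
        raise SelectionError("empty selection string")
    mask = _SelParser(structure, _tokenize(selection), helix_map).parse()
    return AtomGroup(structure, np.flatnonzero(mask))


# ---------------------------------------------------------------------------
# Configuration loading
# ---------------------------------------------------------------------------

def _as_range(value, path: str) -> tuple[int, int]:
    if (not isinstance(value, (list, tuple))) or len(value) != 2:
        raise ConfigError(f"{path}: expected [first_residue, last_residue]")
    return int(value[0]), int(value[1])


def load_config(path: str | Path) -> AnalysisConfig:
    """Load and validate an AnalysisConfig from YAML or JSON.

    Defaults (filled when absent): salt-bridge cutoff 4.0 Å, H-bond
    3.5 Å / 30°, stacking 5.0 Å / 30°, gap 6.0 Å with a 10-frame minimum
    duration, frame window = last 80% of frames, ψ on Cα with mean
    absolute deviation, reporting floor 5%.
    """
    from .interactions import InteractionSpec  # deferred: avoids import cycle

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")

    if "helix_map" not in raw:
        raise ConfigError("helix_map: required")
    hm_raw = raw["helix_map"]
    if not isinstance(hm_raw, Mapping) or not hm_raw:
        raise ConfigError("helix_map: must be a non-empty mapping of segment -> [lo, hi]")
    segments = {str(k): _as_range(v, f"helix_map.{k}") for k, v in hm_raw.items()}
    helix_map = HelixMap(segments=segments,
                         helix_names=frozenset(raw["helix_names"]) if "helix_names" in raw else None)

    domain_map = {str(k): str(v) for k, v in raw.get("domain_map", {}).items()}
    for seg in domain_map:
        if seg not in helix_map.segments:
            raise ConfigError(f"domain_map.{seg}: unknown segment")

    triplet_offsets = {}
    for frame_name, offs in raw.get("triplet_offsets", {}).items():
        if (not isinstance(offs, (list, tuple))) or len(offs) != 3:
            raise ConfigError(f"triplet_offsets.{frame_name}: expected three integers")
        triplet_offsets[str(frame_name)] = tuple(int(o) for o in offs)

    interactions = []
    for i, item in enumerate(raw.get("interactions", [])):
        if not isinstance(item, Mapping):
            raise ConfigError(f"interactions[{i}]: expected a mapping")
        try:
            interactions.append(InteractionSpec(
                kind=str(item["type"]),
                sel_a=str(item["a"]),
                sel_b=str(item["b"]),
                label_a=str(item.get("label_a", item["a"])),
                label_b=str(item.get("label_b", item["b"])),
                cutoff_overrides={str(k): float(v) for k, v in item.get("cutoffs", {}).items()},
            ))
        except KeyError as exc:
            raise ConfigError(f"interactions[{i}]: missing field {exc}") from None

    fw_raw = raw.get("frame_window", {})
    if isinstance(fw_raw, Mapping):
        frame_window = FrameWindow(start=fw_raw.get("start", 0.2), end=fw_raw.get("end", 1.0))
    elif isinstance(fw_raw, (list, tuple)) and len(fw_raw) == 2:
        frame_window = FrameWindow(start=fw_raw[0], end=fw_raw[1])
    else:
        raise ConfigError("frame_window: expected {start, end} or [start, end]")

    cut_raw = raw.get("cutoffs", {})
    if not isinstance(cut_raw, Mapping):
        raise ConfigError("cutoffs: expected a mapping")
    known = {f for f in Cutoffs.__dataclass_fields__}
    for k in cut_raw:
        if k not in known:
            raise ConfigError(f"cutoffs.{k}: unknown cutoff")
    cutoffs = Cutoffs(**{k: float(v) for k, v in cut_raw.items()})

    distance_pairs = []
    for i, item in enumerate(raw.get("distance_pairs", [])):
        if not isinstance(item, Mapping) or "a" not in item or "b" not in item:
            raise ConfigError(f"distance_pairs[{i}]: expected mapping with 'a' and 'b'")
        distance_pairs.append((str(item.get("label", f"pair{i}")), str(item["a"]), str(item["b"])))

    solvent_groups = None
    if "solvent_groups" in raw:
        sg = raw["solvent_groups"]
        if (not isinstance(sg, (list, tuple))) or len(sg) != 2:
            raise ConfigError("solvent_groups: expected [selection_a, selection_b]")
        solvent_groups = (str(sg[0]), str(sg[1]))

    return AnalysisConfig(
        helix_map=helix_map,
        domain_map=domain_map,
        triplet_offsets=triplet_offsets,
        triplets=[int(t) for t in raw.get("triplets", [])],
        triplet_atom=str(raw.get("triplet_atom", "CA")),
        psi_mode=str(raw.get("psi_mode", "mean_abs")),
        interactions=interactions,
        frame_window=frame_window,
        stride=int(raw.get("stride", 1)),
        cutoffs=cutoffs,
        rmsf_selection=str(raw.get("rmsf_selection", "name CA")),
        distance_pairs=distance_pairs,
        gap_min_duration=int(raw.get("gap_min_duration", 10)),
        solvent_groups=solvent_groups,
        report_floor=float(raw.get("report_floor", 5.0)),
        out_dir=raw.get("out_dir"),
    )
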