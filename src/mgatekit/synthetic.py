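"""Synthetic toy-carrier structures and trajectories with exact ground truth.

The generator emulates, at toy scale, the structural setting of a
three-domain mitochondrial-carrier fold: six ideal α-helical Cα traces
(1.5 Å rise, 100° twist per residue, 2.3 Å helix radius) arranged as
three two-helix domains at 0°, 120° and 240° around the bundle axis, so
the reference structure is exactly C3-symmetric unless asymmetry is
injected by rotating and/or radially shifting domain 1.

Salt-bridge dynamics are emulated by *channels*: pairs of charge-site
pseudo-atoms whose separation switches between an "on" band (d_on,
default 3 Å) and an "off" band (d_off, default 8 Å) following a
two-state Markov process with per-frame transition probabilities k_on
and k_off.  Jitter within each band is clamped to ±3σ so that the bands
can never straddle the salt-bridge detection cutoff: downstream
occupancy analysis must recover the realized state sequence with zero
errors, which is what makes the ground truth exact.

Each frame adds isotropic Gaussian positional noise (σ = noise_sigma)
to every atom, and optionally resamples solvent pseudo-oxygens
uniformly within a slab near a designated interface.  One global seed
expands into independent per-component seeds (noise, each channel,
solvent), so adding a channel never changes another component's
realization.

There are no forces, membrane or thermostat here, and no attempt to
reproduce any real carrier's occupancies: the generator exists to give
the analysis stack inputs whose correct answers are known exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, DataError
from .model_io import (
    Atom,
    HelixMap,
    Residue,
    Structure,
    Trajectory,
    write_structure,
    write_trajectory,
)
from .symmetry import TripletMap, psi

__all__ = [
    "ChannelSpec",
    "SolventSpec",
    "ToyCarrierSpec",
    "GroundTruth",
    "build_toy_carrier",
    "markov_states",
    "simulate_trajectory",
    "generate_system",
]

HELIX_RADIUS = 2.3        # Å, Cα helix radius of an ideal α-helix
CHANNEL_SITE_OFFSET = 1.0  # Å, charge site sits this far from its Cα


@dataclass
class ChannelSpec:
    """A two-state contact channel between two charge sites.

    ``res_a`` holds the static site; the site of ``res_b`` is re-placed
    every frame on the reference inter-site axis at d_on or d_off
    (± clamped jitter) according to the Markov state.  k_on is the
    per-frame off→on transition probability, k_off the reverse.
    """

    res_a: int
    res_b: int
    k_on: float
    k_off: float
    d_on: float = 3.0
    d_off: float = 8.0
    jitter: float = 0.2
    initial_state: bool = False
    site_a: str = "CS"
    site_b: str = "CS"
    name: str = ""

    def __post_init__(self) -> None:
        for p in (self.k_on, self.k_off):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"channel {self.res_a}:{self.res_b}: probabilities must be in [0, 1]")
        if self.jitter < 0:
            raise ConfigError("channel jitter must be >= 0")
        if not self.name:
            self.name = f"{self.res_a}:{self.res_b}"

    def validate_bands(self, detection_cutoff: float) -> None:
        """On/off bands must sit on opposite sides of the detection cutoff."""
        if not (self.d_on + 3 * self.jitter < detection_cutoff < self.d_off - 3 * self.jitter):
            raise ConfigError(
                f"channel {self.name}: bands overlap the detection cutoff "
                f"(need d_on + 3·jitter < {detection_cutoff} < d_off − 3·jitter; "
                f"got d_on={self.d_on}, d_off={self.d_off}, jitter={self.jitter})"
            )


@dataclass
class SolventSpec:
    """Solvent pseudo-oxygens resampled uniformly per frame in a slab."""

    count: int
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    z_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ConfigError("solvent count must be >= 1")
        for name in ("x_range", "y_range", "z_range"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ConfigError(f"solvent {name}: empty interval")


@dataclass
class ToyCarrierSpec:
    """Parameters of the toy pseudo-symmetric carrier."""

    n_domains: int = 3
    helices_per_domain: int = 2
    helix_length: int = 20
    bundle_radius: float = 12.0
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    helix_separation_deg: float = 50.0
    domain1_rotation: float = 0.0
    domain1_radial_shift: float = 0.0
    noise_sigma: float = 0.0
    n_frames: int = 1
    seed: int = 0
    channels: list[ChannelSpec] = field(default_factory=list)
    solvent: SolventSpec | None = None
    salt_bridge_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.n_domains != 3 or self.helices_per_domain != 2:
            raise ConfigError("the toy carrier is a three-domain, six-helix bundle")
        if self.helix_length < 4:
            raise ConfigError("helix_length must be >= 4")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        seen: set[tuple[int, str]] = set()
        for ch in self.channels:
            ch.validate_bands(self.salt_bridge_cutoff)
            for key in ((ch.res_a, ch.site_a), (ch.res_b, ch.site_b)):
                if key in seen:
                    raise ConfigError(
                        f"charge site {key[1]} of residue {key[0]} claimed by two channels"
                    )
                seen.add(key)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None) -> "ToyCarrierSpec":
        """Build a spec from a plain mapping (YAML/JSON payload)."""
        raw = dict(raw)
        channels = [ChannelSpec(**c) for c in raw.pop("channels", [])]
        solvent_raw = raw.pop("solvent", None)
        solvent = None
        if solvent_raw is not None:
            solvent = SolventSpec(
                count=int(solvent_raw["count"]),
                x_range=tuple(solvent_raw["x_range"]),
                y_range=tuple(solvent_raw["y_range"]),
                z_range=tuple(solvent_raw["z_range"]),
            )
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown toy-carrier fields: {sorted(unknown)}")
        if seed is not None:
            raw["seed"] = int(seed)
        return cls(channels=channels, solvent=solvent, **raw)

    @property
    def n_helices(self) -> int:
        return self.n_domains * self.helices_per_domain

    @property
    def n_protein_residues(self) -> int:
        return self.n_helices * self.helix_length

    def helix_range(self, k: int) -> tuple[int, int]:
        """Inclusive residue range of helix k (0-based helix index)."""
        return k * self.helix_length + 1, (k + 1) * self.helix_length


@dataclass
class GroundTruth:
    """Everything the generator knows that analyses must recover."""

    channel_states: dict[str, np.ndarray]
    realized_fractions: dict[str, float]
    true_psi: dict[int, float]
    noise_sigma: float

    def __post_init__(self) -> None:
        for name, states in self.channel_states.items():
            states = np.asarray(states, dtype=bool)
            self.channel_states[name] = states
            frac = float(states.mean())
            if abs(frac - self.realized_fractions[name]) > 1e-12:
                raise DataError(f"channel {name}: realized fraction inconsistent with states")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channel_states": {k: v.astype(int).tolist() for k, v in self.channel_states.items()},
            "realized_fractions": self.realized_fractions,
            "true_psi": {str(k): v for k, v in self.true_psi.items()},
            "noise_sigma": self.noise_sigma,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            channel_states={k: np.array(v, dtype=bool) for k, v in raw["channel_states"].items()},
            realized_fractions=raw["realized_fractions"],
            true_psi={int(k): float(v) for k, v in raw["true_psi"].items()},
            noise_sigma=float(raw["noise_sigma"]),
        )


# ---------------------------------------------------------------------------
# Structure construction
# ---------------------------------------------------------------------------

def _rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _domain0_ca_coords(spec: ToyCarrierSpec) -> np.ndarray:
    """Cα coordinates of domain 1's two helices (odd up, even down)."""
    L = spec.helix_length
    coords = np.empty((2 * L, 3))
    for parity in (0, 1):
        phi = np.radians((-1 if parity == 0 else 1) * spec.helix_separation_deg / 2.0)
        center = spec.bundle_radius * np.array([np.cos(phi), np.sin(phi), 0.0])
        direction = 1.0 if parity == 0 else -1.0
        for i in range(L):
            alpha = phi + np.radians(spec.twist_per_residue) * i
            z = direction * spec.rise_per_residue * (i - (L - 1) / 2.0)
            coords[parity * L + i] = center + np.array(
                [HELIX_RADIUS * np.cos(alpha), HELIX_RADIUS * np.sin(alpha), z]
            )
    return coords


def _reference_ca_coords(spec: ToyCarrierSpec) -> np.ndarray:
    """All 6·L Cα positions; domain-1 asymmetry applied last."""
    d0 = _domain0_ca_coords(spec)
    parts = [d0 @ _rot_z(120.0 * d).T for d in range(3)]
    if spec.domain1_rotation != 0.0:
        parts[0] = parts[0] @ _rot_z(spec.domain1_rotation).T
    if spec.domain1_radial_shift != 0.0:
        parts[0] = parts[0] + np.array([spec.domain1_radial_shift, 0.0, 0.0])
    return np.concatenate(parts, axis=0)


def _channel_site_reference(ca: np.ndarray, ch: ChannelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference positions of the two charge sites and their unit axis."""
    a = ca[ch.res_a - 1]
    b = ca[ch.res_b - 1]
    axis = b - a
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ConfigError(f"channel {ch.name}: charge-site residues coincide")
    u = axis / norm
    site_a = a + u * CHANNEL_SITE_OFFSET
    site_b = site_a + u * ch.d_off  # reference structure starts in the off band
    return site_a, site_b, u


def build_toy_carrier(spec: ToyCarrierSpec) -> tuple[Structure, HelixMap, TripletMap]:
    """Construct the reference toy structure, its segment map and triplet map.

    Residues are numbered consecutively helix by helix (H1 first), one
    Cα per residue, plus one charge-site pseudo-atom per residue
    referenced by a channel and optional solvent placeholders.  Channel
    residues are named ARG (static side) and ASP (moving side) so that
    salt-bridge role resolution and basic×acidic auto-enumeration treat
    them like their all-atom counterparts.
    """
    L = spec.helix_length
    n_res = spec.n_protein_residues
    ca = _reference_ca_coords(spec)

    res_names = {r: "ALA" for r in range(1, n_res + 1)}
    channel_sites: dict[tuple[int, str], np.ndarray] = {}
    for ch in spec.channels:
        for r in (ch.res_a, ch.res_b):
            if not 1 <= r <= n_res:
                raise ConfigError(
                    f"channel {ch.name}: residue {r} outside the helices (1..{n_res})"
                )
        site_a, site_b, _u = _channel_site_reference(ca, ch)
        channel_sites[(ch.res_a, ch.site_a)] = site_a
        channel_sites[(ch.res_b, ch.site_b)] = site_b
        res_names[ch.res_a] = "ARG"
        res_names[ch.res_b] = "ASP"

    residues = []
    serial = 0
    for r in range(1, n_res + 1):
        serial += 1
        atoms = [Atom(serial, "CA", "C", ca[r - 1])]
        for (rr, site), pos in channel_sites.items():
            if rr == r:
                serial += 1
                atoms.append(Atom(serial, site, "N" if res_names[r] == "ARG" else "O", pos))
        residues.append(Residue(r, res_names[r], "A", atoms))

    if spec.solvent is not None:
        center = np.array([
            np.mean(spec.solvent.x_range),
            np.mean(spec.solvent.y_range),
            np.mean(spec.solvent.z_range),
        ])
        for w in range(spec.solvent.count):
            serial += 1
            residues.append(Residue(
                n_res + 1 + w, "SOL", "W", [Atom(serial, "O", "O", center)]
            ))

    structure = Structure(residues, title="toy carrier")
    helix_map = HelixMap(
        segments={f"H{k + 1}": spec.helix_range(k) for k in range(spec.n_helices)},
        default_segment="loop",
    )
    triplet_map = TripletMap(
        offsets={"odd": (0, 2 * L, 4 * L), "even": (0, 2 * L, 4 * L)},
        helix_map=helix_map,
        segments={"odd": ("H1", "H3", "H5"), "even": ("H2", "H4", "H6")},
    )
    return structure, helix_map, triplet_map


# ---------------------------------------------------------------------------
# Stochastic engines
# ---------------------------------------------------------------------------

def markov_states(
    k_on: float,
    k_off: float,
    n_frames: int,
    initial_state: bool = False,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Boolean state sequence of a two-state Markov chain.

    State True ("on") flips to False with probability k_off per frame;
    False flips to True with probability k_on.  Starting from
    ``initial_state``, one transition is attempted per frame and the
    post-transition state is recorded.  The stationary on probability
    is k_on / (k_on + k_off).  Reproducible for a fixed seed.
    """
    for p in (k_on, k_off):
        if not 0.0 <= p <= 1.0:
            raise ConfigError("transition probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random(n_frames)
    states = np.empty(n_frames, dtype=bool)
    state = bool(initial_state)
    for i in range(n_frames):
        if state:
            state = not (draws[i] < k_off)
        else:
            state = draws[i] < k_on
        states[i] = state
    return states


def _component_seed(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key))


def simulate_trajectory(
    structure: Structure,
    spec: ToyCarrierSpec,
) -> tuple[Trajectory, GroundTruth]:
    """Realize the stochastic toy trajectory over the reference structure.

    Per frame: isotropic Gaussian noise (σ = noise_sigma) on every atom;
    each channel's moving charge site re-placed on the reference
    inter-site axis at d_on or d_off plus jitter clamped to ±3σ_jitter;
    solvent pseudo-oxygens resampled uniformly in their slab.  The
    returned ground truth records the per-channel state sequences, the
    realized on-fractions, the true ψ of every triplet of the noiseless
    reference, and the noise σ.
    """
    n_frames = spec.n_frames
    n_atoms = structure.n_atoms
    ref = structure.coords

    rng_noise = np.random.default_rng(_component_seed(spec.seed, 0))
    coords = np.empty((n_frames, n_atoms, 3))
    if spec.noise_sigma > 0:
        # chunked so a long trajectory does not need a second full-size buffer
        step = max(1, int(2e7 // max(n_atoms * 3, 1)))
        for s in range(0, n_frames, step):
            block = slice(s, min(s + step, n_frames))
            coords[block] = ref + rng_noise.normal(
                0.0, spec.noise_sigma, (block.stop - block.start, n_atoms, 3)
            )
    else:
        coords[:] = ref

    ca_ref = np.array([structure.coords[structure.atom_index(r, "CA")]
                       for r in range(1, spec.n_protein_residues + 1)])

    channel_states: dict[str, np.ndarray] = {}
    for ch in spec.channels:
        seed_seq = _component_seed(spec.seed, 1, ch.res_a, ch.res_b)
        state_seed, jitter_seed = seed_seq.spawn(2)
        states = markov_states(ch.k_on, ch.k_off, n_frames, ch.initial_state, state_seed)
        channel_states[ch.name] = states

        rng_j = np.random.default_rng(jitter_seed)
        jitter = rng_j.normal(0.0, ch.jitter, n_frames) if ch.jitter > 0 else np.zeros(n_frames)
        jitter = np.clip(jitter, -3 * ch.jitter, 3 * ch.jitter)
        dist = np.where(states, ch.d_on, ch.d_off) + jitter

        _sa, _sb, u = _channel_site_reference(ca_ref, ch)
        ia = structure.atom_index(ch.res_a, ch.site_a)
        ib = structure.atom_index(ch.res_b, ch.site_b)
        coords[:, ib, :] = coords[:, ia, :] + dist[:, None] * u

    if spec.solvent is not None:
        rng_s = np.random.default_rng(_component_seed(spec.seed, 2))
        sol_mask = structure.res_names.astype(str) == "SOL"
        sol_idx = np.flatnonzero(sol_mask)
        lows = np.array([spec.solvent.x_range[0], spec.solvent.y_range[0], spec.solvent.z_range[0]])
        highs = np.array([spec.solvent.x_range[1], spec.solvent.y_range[1], spec.solvent.z_range[1]])
        coords[:, sol_idx, :] = rng_s.uniform(lows, highs, (n_frames, len(sol_idx), 3))

    L = spec.helix_length
    true_psi = {}
    for t in range(1, L + 1):
        p1, p2, p3 = ca_ref[t - 1], ca_ref[t + 2 * L - 1], ca_ref[t + 4 * L - 1]
        true_psi[t] = psi(p1, p2, p3)

    truth = GroundTruth(
        channel_states=channel_states,
        realized_fractions={k: float(v.mean()) for k, v in channel_states.items()},
        true_psi=true_psi,
        noise_sigma=spec.noise_sigma,
    )
    times = 10.0 * (1.0 + np.arange(n_frames))  # ps, fixed 10 ps save stride
    return Trajectory(topology=structure, coords=coords, frame_times=times), truth


def generate_system(spec: ToyCarrierSpec, out_dir: str | Path) -> dict[str, Path]:
    """Build + simulate + write reference PDB, multi-model trajectory PDB
    and ground-truth JSON into ``out_dir``.  Returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    structure, _hm, _tm = build_toy_carrier(spec)
    trajectory, truth = simulate_trajectory(structure, spec)
    paths = {
        "reference": out / "reference.pdb",
        "trajectory": out / "trajectory.pdb",
        "ground_truth": out / "ground_truth.json",
    }
    write_structure(structure, paths["reference"])
    write_trajectory(trajectory, paths["trajectory"])
    truth.to_json(paths["ground_truth"])
    return paths
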