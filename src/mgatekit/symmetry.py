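"""Triplet-based C3 pseudo-symmetry deviation (ψ).

A carrier with three homologous domains places one residue of each
domain at structurally equivalent positions; such a trio is a
*triplet*, indexed by the residue number of its domain-1 member.  For a
perfectly threefold-symmetric backbone the three Cα atoms of a triplet
form an equilateral triangle.  ψ quantifies the departure from that
ideal as the mean absolute deviation of the triangle's interior angles
from 60°, in degrees: ψ = 0 for any equilateral configuration, and
ψ → 80° as the triangle degenerates towards collinearity (angles
180°, 0°, 0°).  ψ is internal to each triangle — invariant under rigid
motion and uniform scaling — so no superposition is applied.

A root-mean-square variant (deviation = RMS of |θᵢ − 60°|) is offered
through ``mode="rms"`` for cross-checking against conventions that
average quadratically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, DegenerateTriangleError
from .model_io import FrameWindow, HelixMap, Trajectory

__all__ = [
    "TripletMap",
    "SymmetrySeries",
    "triplet_members",
    "triangle_angles",
    "psi",
    "psi_series",
    "psi_summary",
]

_MIN_SIDE = 1e-6  # Å; below this a triplet triangle counts as degenerate


def triplet_members(t: int, offsets: tuple[int, int, int]) -> tuple[int, int, int]:
    """Residue numbers of triplet ``t`` given per-domain offsets.

    The triplet is indexed by its domain-1 residue number; the members
    on the other two domains sit at fixed sequence offsets, e.g.
    offsets ``(0, +105, +202)`` map triplet 33 to residues
    (33, 138, 235).
    """
    if len(offsets) != 3:
        raise ConfigError("triplet offsets must have exactly three entries")
    return (t + int(offsets[0]), t + int(offsets[1]), t + int(offsets[2]))


@dataclass
class TripletMap:
    """Triplet index → three symmetric residue numbers.

    Offsets are kept separately per frame of reference ("odd" for
    odd-numbered helices, "even" for even ones) because the symmetric
    copies on odd and even helices sit at different sequence offsets.
    Explicit per-triplet residue triples override the offset rule.
    """

    offsets: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    explicit: dict[int, tuple[int, int, int]] = field(default_factory=dict)
    helix_map: HelixMap | None = None
    segments: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def members(self, t: int, frame_of_reference: str = "odd") -> tuple[int, int, int]:
        if t in self.explicit:
            trio = self.explicit[t]
        else:
            if frame_of_reference not in self.offsets:
                raise ConfigError(
                    f"no triplet offsets configured for frame of reference "
                    f"'{frame_of_reference}'"
                )
            trio = triplet_members(t, self.offsets[frame_of_reference])
        self._check_domains(t, trio, frame_of_reference)
        return trio

    def _check_domains(self, t: int, trio: tuple[int, int, int], frame: str) -> None:
        if self.helix_map is None:
            return
        segs = [self.helix_map.segment_of(r) for r in trio]
        expected = self.segments.get(frame)
        if expected is not None:
            for r, seg, exp in zip(trio, segs, expected):
                if seg != exp:
                    raise ConfigError(
                        f"triplet {t}: residue {r} falls in segment '{seg}', "
                        f"outside its expected segment '{exp}'"
                    )
        elif len(set(segs)) != 3:
            raise ConfigError(
                f"triplet {t}: members {trio} do not lie in three distinct segments "
                f"(got {segs})"
            )


@dataclass
class SymmetrySeries:
    """Per-triplet, per-frame ψ values in degrees.

    ``values`` has shape (n_frames, n_triplets), column order matching
    ``triplets``.
    """

    triplets: list[int]
    values: np.ndarray
    frame_indices: np.ndarray
    mode: str = "mean_abs"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if self.values.shape != (len(self.frame_indices), len(self.triplets)):
            raise DataError("symmetry series shape mismatch")
        if np.any(self.values < -1e-12):
            raise DataError("negative ψ value")

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: frame, triplet, psi_deg."""
        f, t = np.meshgrid(self.frame_indices, self.triplets, indexing="ij")
        return pd.DataFrame({
            "frame": f.ravel(),
            "triplet": t.ravel(),
            "psi_deg": self.values.ravel(),
        })


def _angles_from_points(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Interior angles (deg) at p1, p2, p3 for stacked point arrays (..., 3)."""
    v12 = p2 - p1
    v13 = p3 - p1
    v23 = p3 - p2
    a = np.linalg.norm(v23, axis=-1)  # side opposite p1
    b = np.linalg.norm(v13, axis=-1)
    c = np.linalg.norm(v12, axis=-1)
    if np.any(np.minimum(np.minimum(a, b), c) < _MIN_SIDE):
        raise DegenerateTriangleError(
            "coincident points: triangle side below 1e-6 Å — data corruption, "
            "not extreme asymmetry"
        )
    cos1 = np.sum(v12 * v13, axis=-1) / (c * b)
    cos2 = np.sum(-v12 * v23, axis=-1) / (c * a)
    cos3 = np.sum(-v13 * -v23, axis=-1) / (b * a)
    ang = np.degrees(np.arccos(np.clip(np.stack([cos1, cos2, cos3], axis=-1), -1.0, 1.0)))
    return ang


def triangle_angles(p1, p2, p3) -> tuple[float, float, float]:
    """Interior angles of the triangle (p1, p2, p3) in degrees.

    The three angles sum to 180° to within numerical round-off.
    Raises :class:`DegenerateTriangleError` if any two points coincide
    (pairwise distance below 1e-6 Å).
    """
    ang = _angles_from_points(
        np.asarray(p1, dtype=float),
        np.asarray(p2, dtype=float),
        np.asarray(p3, dtype=float),
    )
    return float(ang[0]), float(ang[1]), float(ang[2])


def psi(p1, p2, p3, mode: str = "mean_abs") -> float:
    """C3-symmetry deviation of one triangle, degrees.

    ``mean_abs`` (default): mean of |θᵢ − 60°| over the three interior
    angles.  ``rms``: root-mean-square of the same deviations.
    """
    ang = np.array(triangle_angles(p1, p2, p3))
    dev = np.abs(ang - 60.0)
    if mode == "mean_abs":
        return float(np.mean(dev))
    if mode == "rms":
        return float(np.sqrt(np.mean(dev ** 2)))
    raise ConfigError(f"unknown psi mode '{mode}'")


def psi_series(
    trajectory: Trajectory,
    triplet_map: TripletMap,
    triplets: list[int],
    atom_name: str = "CA",
    frame_of_reference: str = "odd",
    mode: str = "mean_abs",
) -> SymmetrySeries:
    """ψ for every configured triplet in every frame.

    No superposition is applied: ψ only depends on the internal geometry
    of each triplet triangle.
    """
    if not triplets:
        raise ConfigError("no triplets requested")
    top = trajectory.topology
    idx = np.empty((len(triplets), 3), dtype=int)
    for k, t in enumerate(triplets):
        for j, resnum in enumerate(triplet_map.members(t, frame_of_reference)):
            try:
                idx[k, j] = top.atom_index(resnum, atom_name)
            except DataError as exc:
                raise DataError(f"triplet {t}: {exc}") from exc

    p = trajectory.coords[:, idx, :]          # (F, T, 3 members, 3)
    ang = _angles_from_points(p[:, :, 0], p[:, :, 1], p[:, :, 2])  # (F, T, 3)
    dev = np.abs(ang - 60.0)
    if mode == "mean_abs":
        vals = dev.mean(axis=-1)
    elif mode == "rms":
        vals = np.sqrt((dev ** 2).mean(axis=-1))
    else:
        raise ConfigError(f"unknown psi mode '{mode}'")
    return SymmetrySeries(
        triplets=list(triplets),
        values=vals,
        frame_indices=np.arange(trajectory.n_frames),
        mode=mode,
    )


def psi_summary(series: SymmetrySeries, frame_window: FrameWindow | None = None) -> pd.DataFrame:
    """Mean and SD of ψ per triplet over the analysis window."""
    n = len(series.frame_indices)
    if frame_window is None:
        i0, i1 = 0, n
    else:
        i0, i1 = frame_window.resolve(n)
    window = series.values[i0:i1]
    if window.size == 0:
        raise ConfigError("empty frame window for ψ summary")
    return pd.DataFrame({
        "triplet": series.triplets,
        "mean_psi_deg": window.mean(axis=0),
        "sd_psi_deg": window.std(axis=0, ddof=0),
    })
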