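"""Superposition, RMSF, minimum-distance series, gap events, solvent counts.

The superposition is the standard least-squares rigid fit (proper
rotation, det = +1), delegated to scipy's Kabsch-style
``Rotation.align_vectors``.  RMSF follows trajectory-analysis
convention: frames are fitted onto the window-average structure with
one refinement pass (average → re-fit → re-average) before the
fluctuation of each atom about its mean position is taken.

Gap events are maximal runs of frames during which an interface
distance exceeds an openness cutoff for at least a minimum duration —
the footprint a transiently opening crevice leaves in a minimum-
distance series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ConfigError, DataError, SelectionError
from .model_io import AtomGroup, FrameWindow, HelixMap, Structure, Trajectory, select_atoms

__all__ = [
    "RigidTransform",
    "GapEvent",
    "superpose",
    "apply_transform",
    "rmsf",
    "min_distance_series",
    "gap_events",
    "solvent_count_series",
    "SOLVENT_RESNAMES",
]

SOLVENT_RESNAMES = ("HOH", "WAT", "SOL")


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ R @ x + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class GapEvent:
    """One contiguous open interval: inclusive frame bounds, the widest
    gap reached, and (optionally) the mean bridging-solvent count."""

    start_frame: int
    end_frame: int
    max_gap: float
    mean_solvent_count: float | None = None

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise DataError("gap event with start > end")


def superpose(
    mobile_coords: np.ndarray,
    reference_coords: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Optimal least-squares rigid fit of mobile onto reference.

    Returns the transform and the RMSD over the fit group after
    applying it.  Requires at least three non-collinear fit atoms.
    """
    mob = np.asarray(mobile_coords, dtype=float)
    ref = np.asarray(reference_coords, dtype=float)
    if fit_indices is not None:
        mob_fit, ref_fit = mob[fit_indices], ref[fit_indices]
    else:
        mob_fit, ref_fit = mob, ref
    if mob_fit.shape != ref_fit.shape:
        raise DataError("fit groups must have equal atom counts")
    if len(mob_fit) < 3:
        raise DataError("superposition needs at least 3 fit atoms")
    cm, cr = mob_fit.mean(axis=0), ref_fit.mean(axis=0)
    mc, rc = mob_fit - cm, ref_fit - cr
    if np.linalg.matrix_rank(rc, tol=1e-8) < 2:
        raise DataError("degenerate fit group (collinear or coincident atoms)")
    rot, _rssd = Rotation.align_vectors(rc, mc)
    R = rot.as_matrix()
    t = cr - R @ cm
    transform = RigidTransform(rotation=R, translation=t)
    fitted = transform.apply(mob_fit)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_fit) ** 2, axis=1))))
    return transform, rmsd


def apply_transform(transform: RigidTransform, coords: np.ndarray) -> np.ndarray:
    return transform.apply(coords)


def rmsf(
    trajectory: Trajectory,
    selection: str = "name CA",
    frame_window: FrameWindow | None = None,
    fit: bool = True,
    fit_selection: str | None = None,
    helix_map: HelixMap | None = None,
) -> pd.DataFrame:
    """Per-residue RMSF (Å) of the selected atoms over the window.

    With ``fit`` enabled each window frame is superposed (on
    ``fit_selection``, default the RMSF selection itself) onto the
    window-average structure, the average is rebuilt from the fitted
    frames, the original frames are re-fitted once onto that refined
    average, and RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩) is taken about the
    final mean.  Columns: residue, atom, rmsf_angstrom.
    """
    group = select_atoms(trajectory.topology, selection, helix_map)
    if len(group) == 0:
        raise SelectionError(f"RMSF selection '{selection}' matches no atoms")
    n = trajectory.n_frames
    i0, i1 = (frame_window or FrameWindow(0, n)).resolve(n)
    if i1 - i0 < 2:
        raise ConfigError("RMSF window must span at least 2 frames")
    sel_idx = group.indices
    if fit_selection is None:
        fit_idx = sel_idx
    else:
        fit_group = select_atoms(trajectory.topology, fit_selection, helix_map)
        if len(fit_group) == 0:
            raise SelectionError(f"fit selection '{fit_selection}' matches no atoms")
        fit_idx = fit_group.indices
    frames_sel = trajectory.coords[i0:i1, sel_idx, :]
    frames_fit = trajectory.coords[i0:i1, fit_idx, :]

    if fit:
        def _fit_pass(reference_fit: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            out_sel = np.empty_like(frames_sel)
            out_fit = np.empty_like(frames_fit)
            for k in range(len(frames_sel)):
                transform, _ = superpose(frames_fit[k], reference_fit)
                out_sel[k] = transform.apply(frames_sel[k])
                out_fit[k] = transform.apply(frames_fit[k])
            return out_sel, out_fit

        # pass 1: fit onto the raw average, pass 2: refit onto the refined one
        fitted_sel, fitted_fit = _fit_pass(frames_fit.mean(axis=0))
        fitted_sel, _ = _fit_pass(fitted_fit.mean(axis=0))
        frames_out = fitted_sel
    else:
        frames_out = frames_sel

    mean_pos = frames_out.mean(axis=0)
    values = np.sqrt(np.mean(np.sum((frames_out - mean_pos) ** 2, axis=2), axis=0))
    top = trajectory.topology
    return pd.DataFrame({
        "residue": top.res_numbers[sel_idx],
        "atom": top.atom_names[sel_idx].astype(str),
        "rmsf_angstrom": values,
    })


def _heavy_indices(structure: Structure, group: AtomGroup) -> np.ndarray:
    elements = np.char.upper(structure.elements[group.indices].astype(str))
    return group.indices[elements != "H"]


def min_distance_series(
    trajectory: Trajectory,
    group_a: AtomGroup | str,
    group_b: AtomGroup | str,
    helix_map: HelixMap | None = None,
    chunk: int = 2000,
) -> np.ndarray:
    """Per-frame minimum heavy-atom distance between two disjoint groups (Å)."""
    top = trajectory.topology
    if isinstance(group_a, str):
        group_a = select_atoms(top, group_a, helix_map)
    if isinstance(group_b, str):
        group_b = select_atoms(top, group_b, helix_map)
    idx_a = _heavy_indices(top, group_a)
    idx_b = _heavy_indices(top, group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise SelectionError("empty heavy-atom group for distance series")
    if np.intersect1d(idx_a, idx_b).size:
        raise SelectionError("distance groups overlap")
    out = np.empty(trajectory.n_frames)
    for s in range(0, trajectory.n_frames, chunk):
        block = trajectory.coords[s:s + chunk]
        d = np.linalg.norm(
            block[:, idx_a, None, :] - block[:, None, idx_b, :], axis=-1
        )
        out[s:s + chunk] = d.min(axis=(1, 2))
    return out


def gap_events(
    series: np.ndarray,
    open_cutoff: float = 6.0,
    min_duration_frames: int = 10,
    solvent_counts: np.ndarray | None = None,
) -> list[GapEvent]:
    """Maximal runs of frames with distance strictly above the cutoff,
    discarding runs shorter than the minimum duration.  Events are
    non-overlapping and ordered; frame bounds are inclusive."""
    if open_cutoff <= 0:
        raise ConfigError("open_cutoff must be > 0")
    if min_duration_frames < 1:
        raise ConfigError("min_duration_frames must be >= 1")
    series = np.asarray(series, dtype=float)
    open_mask = series > open_cutoff
    events: list[GapEvent] = []
    padded = np.concatenate([[False], open_mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < min_duration_frames:
            continue
        mean_solv = (
            float(np.mean(solvent_counts[start:stop]))
            if solvent_counts is not None else None
        )
        events.append(GapEvent(
            start_frame=int(start),
            end_frame=int(stop - 1),
            max_gap=float(series[start:stop].max()),
            mean_solvent_count=mean_solv,
        ))
    return events


def solvent_count_series(
    trajectory: Trajectory,
    interface_group_a: AtomGroup | str,
    interface_group_b: AtomGroup | str,
    radius: float = 4.0,
    solvent_resnames: tuple[str, ...] = SOLVENT_RESNAMES,
    helix_map: HelixMap | None = None,
) -> np.ndarray:
    """Per-frame count of bridging solvent: solvent oxygens within
    ``radius`` of BOTH interface groups."""
    top = trajectory.topology
    if isinstance(interface_group_a, str):
        interface_group_a = select_atoms(top, interface_group_a, helix_map)
    if isinstance(interface_group_b, str):
        interface_group_b = select_atoms(top, interface_group_b, helix_map)
    res_names = top.res_names.astype(str)
    elements = np.char.upper(top.elements.astype(str))
    solvent_idx = np.flatnonzero(np.isin(res_names, list(solvent_resnames)) & (elements == "O"))
    if solvent_idx.size == 0:
        raise DataError(
            "no solvent oxygens in topology — run the analysis in solvent-free mode"
        )
    idx_a = _heavy_indices(top, interface_group_a)
    idx_b = _heavy_indices(top, interface_group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise SelectionError("empty interface group for solvent counting")
    counts = np.empty(trajectory.n_frames, dtype=int)
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f]
        sol = frame[solvent_idx]
        da = np.linalg.norm(sol[:, None, :] - frame[idx_a][None, :, :], axis=-1).min(axis=1)
        db = np.linalg.norm(sol[:, None, :] - frame[idx_b][None, :, :], axis=-1).min(axis=1)
        counts[f] = int(np.sum((da <= radius) & (db <= radius)))
    return counts
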