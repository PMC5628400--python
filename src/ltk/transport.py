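"""Ligand transport analysis for flooding trajectories.

Flooding simulations place many ligand copies (here O2) around a protein
and watch for spontaneous entry.  This module measures, per ligand, the
distance to a binding-site reference point over time; detects entrance
events as maximal runs of frames below a distance threshold (6 angstrom
by default, the criterion for a complete entrance to the catalytic metal
site); builds per-voxel occupancy density maps of where the ligands spend
their time; and converts copy numbers to molar concentrations for
bookkeeping of the flooding setup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import MolecularSystem, ScalarGrid, Trajectory, minimum_image

__all__ = [
    "AVOGADRO",
    "DistanceSeries",
    "EntranceEvent",
    "OccupancyMap",
    "ligand_site_distances",
    "detect_entrance_events",
    "residence_statistics",
    "occupancy_density",
    "average_occupancy_maps",
    "molar_concentration",
]

AVOGADRO = 6.02214076e23
_L_PER_CUBIC_ANGSTROM = 1e-27


@dataclass
class DistanceSeries:
    """Per-frame distance from one ligand's centroid to the site point."""

    ligand_id: int
    frames: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.frames.shape != self.distances.shape:
            raise ValueError("frames and distances must be congruent")
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")


@dataclass
class EntranceEvent:
    """A maximal run of frames with the ligand inside the threshold."""

    ligand_id: int
    entry_frame: int
    exit_frame: int

    def __post_init__(self) -> None:
        if self.entry_frame > self.exit_frame:
            raise ValueError("entry_frame must be <= exit_frame")

    @property
    def residence(self) -> int:
        return self.exit_frame - self.entry_frame + 1


@dataclass
class OccupancyMap:
    """Per-voxel fraction of frames with >= 1 ligand atom inside."""

    grid: ScalarGrid
    n_frames: int

    def __post_init__(self) -> None:
        v = self.grid.values
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("occupancy values must lie in [0, 1]")


def _resolve_selection(
    system: MolecularSystem, selection, label: str
) -> np.ndarray:
    if isinstance(selection, dict):
        idx = system.select(**selection)
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError(f"{label} selection matched no atoms")
    return idx


def ligand_site_distances(
    traj: Trajectory,
    ligand_selection,
    site_selection,
) -> list[DistanceSeries]:
    """Centroid-to-site distances per ligand residue per frame.

    ``ligand_selection``/``site_selection`` are either index arrays or
    keyword dicts for :meth:`MolecularSystem.select`.  Ligand atoms are
    grouped by residue — one series per ligand copy, distances measured
    from the residue centroid to the site point (the centroid of the site
    selection).  Minimum-image displacement is used when the trajectory
    carries a box.
    """
    lig_idx = _resolve_selection(traj.topology, ligand_selection, "ligand")
    site_idx = _resolve_selection(traj.topology, site_selection, "site")
    residues = traj.topology.residues
    by_residue: dict[int, list[int]] = {}
    atom_to_res = {}
    for ri, res in enumerate(residues):
        for ai in res.atom_indices:
            atom_to_res[ai] = ri
    for ai in lig_idx:
        by_residue.setdefault(atom_to_res[int(ai)], []).append(int(ai))

    site_point = traj.frames[:, site_idx].mean(axis=1)  # (n_frames, 3)
    out = []
    frame_idx = np.arange(traj.n_frames)
    for lig_id, (ri, atom_ids) in enumerate(sorted(by_residue.items())):
        centroid = traj.frames[:, atom_ids].mean(axis=1)
        delta = minimum_image(centroid - site_point, traj.box)
        out.append(
            DistanceSeries(
                ligand_id=lig_id,
                frames=frame_idx.copy(),
                distances=np.linalg.norm(delta, axis=1),
            )
        )
    return out


def detect_entrance_events(
    series: DistanceSeries,
    threshold: float = 6.0,
    min_frames: int = 1,
) -> list[EntranceEvent]:
    """Maximal runs of consecutive frames with distance < threshold.

    Runs shorter than ``min_frames`` are discarded (default 1: any
    sub-threshold excursion counts as a complete entrance).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    inside = series.distances < threshold
    if not inside.any():
        return []
    padded = np.concatenate([[False], inside, [False]]).astype(int)
    edges = np.flatnonzero(np.diff(padded))
    starts, stops = edges[::2], edges[1::2]
    events = []
    for s, e in zip(starts, stops):
        if e - s >= min_frames:
            events.append(
                EntranceEvent(
                    ligand_id=series.ligand_id,
                    entry_frame=int(series.frames[s]),
                    exit_frame=int(series.frames[e - 1]),
                )
            )
    return events


def residence_statistics(events: Sequence[EntranceEvent]) -> dict[str, float]:
    """Count, mean and max residence (frames) over a set of events."""
    if not events:
        return {"count": 0, "mean_residence": 0.0, "max_residence": 0}
    res = np.array([e.residence for e in events])
    return {
        "count": len(events),
        "mean_residence": float(res.mean()),
        "max_residence": int(res.max()),
    }


def occupancy_density(
    traj: Trajectory,
    ligand_selection,
    spacing: float = 1.0,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> OccupancyMap:
    """Binary per-frame voxel occupancy, averaged over frames.

    A voxel counts as occupied in a frame when at least one selected atom
    center falls inside it; the map value is occupied-frame count divided
    by the number of frames (Volmap-style occupancy, displayed in the
    study's figures at isovalue 0.006).  ``bounds`` defaults to the
    selection's bounding box plus one voxel of margin.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    idx = _resolve_selection(traj.topology, ligand_selection, "ligand")
    pts = traj.frames[:, idx]  # (n_frames, n_sel, 3)
    if bounds is None:
        lo = pts.reshape(-1, 3).min(axis=0) - spacing
        hi = pts.reshape(-1, 3).max(axis=0) + spacing
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    counts = np.zeros(shape)
    n_inside = 0
    for f in range(traj.n_frames):
        ijk = np.floor((pts[f] - lo) / spacing).astype(int)
        ok = np.all((ijk >= 0) & (ijk < shape), axis=1)
        n_inside += int(ok.sum())
        if not ok.any():
            continue
        occupied = np.unique(ijk[ok], axis=0)
        counts[occupied[:, 0], occupied[:, 1], occupied[:, 2]] += 1
    if n_inside == 0:
        warnings.warn("all selected atoms fall outside the map bounds", stacklevel=2)
    # grid origin at voxel centers: lo + spacing/2
    grid = ScalarGrid(
        origin=lo + spacing / 2, spacing=spacing, values=counts / traj.n_frames
    )
    return OccupancyMap(grid=grid, n_frames=traj.n_frames)


def average_occupancy_maps(maps: Sequence[OccupancyMap]) -> OccupancyMap:
    """Frame-count-weighted voxel-wise average of replicate maps.

    All maps must share the same grid geometry (origin, spacing, shape);
    this mirrors averaging an occupancy map over replicate flooding runs.
    """
    if not maps:
        raise ValueError("need at least one map")
    ref = maps[0].grid
    for m in maps[1:]:
        if (
            m.grid.shape != ref.shape
            or not np.allclose(m.grid.origin, ref.origin)
            or not np.isclose(m.grid.spacing, ref.spacing)
        ):
            raise ValueError("maps must share grid geometry to be averaged")
    total_frames = sum(m.n_frames for m in maps)
    values = sum(m.grid.values * m.n_frames for m in maps) / total_frames
    return OccupancyMap(
        grid=ScalarGrid(origin=ref.origin.copy(), spacing=ref.spacing, values=values),
        n_frames=total_frames,
    )


def molar_concentration(n_molecules: int, box_volume: float) -> float:
    """Concentration in mol/L of ``n_molecules`` in ``box_volume`` cubic angstrom.

    c = (n / N_A) / (V * 1e-27 L/A^3).  Ten O2 copies in a 520 000 A^3 box
    give 0.032 M, the flooding concentration used to saturate entry
    sampling.
    """
    if box_volume <= 0:
        raise ValueError("box_volume must be > 0")
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    return (n_molecules / AVOGADRO) / (box_volume * _L_PER_CUBIC_ANGSTROM)
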