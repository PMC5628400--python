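"""Trajectory-ensemble structural analyses.

Superposition removes global rotation/translation by least-squares
fitting each frame's selected atoms onto a reference (Kabsch); RMSD and
RMSF then measure displacement from the reference and fluctuation about
the time mean.  Cross-correlation matrices capture concerted motion
between atoms; hydrogen bonds are scored geometrically (donor-acceptor
distance and donor-hydrogen-acceptor angle) and summarized as the
fraction of frames in which the bond is present, with a report filter at
30% occupancy by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .core import MolecularSystem, Trajectory, minimum_image

__all__ = [
    "RMSFProfile",
    "CorrelationMatrix",
    "HBond",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "rmsf_difference",
    "cross_correlation",
    "hbond_occupancy",
    "filter_hbonds",
]


@dataclass
class RMSFProfile:
    """Per-atom or per-residue RMSF in angstrom."""

    labels: list
    values: np.ndarray
    selection: str
    n_frames: int
    by_residue: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSF must be >= 0")


@dataclass
class CorrelationMatrix:
    """Normalized cross-correlation of positional fluctuations."""

    matrix: np.ndarray
    labels: list
    selection: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.matrix = m


@dataclass
class HBond:
    """A donor-hydrogen-acceptor triple with its frame occupancy."""

    donor: int
    hydrogen: int
    acceptor: int
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


def _resolve(system: MolecularSystem, selection) -> np.ndarray:
    if selection is None:
        return np.arange(system.n_atoms)
    if isinstance(selection, dict):
        return system.select(**selection)
    return np.asarray(selection, dtype=int)


def _check_not_collinear(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("superposition selection is collinear or degenerate")


def superpose(
    traj: Trajectory,
    reference_frame: int = 0,
    selection=None,
) -> Trajectory:
    """Rigid-body least-squares superposition of every frame.

    The optimal rotation is found on the selected atoms (>= 3,
    non-collinear) and applied to all atoms.  Returns a new trajectory;
    the input is left untouched.
    """
    sel = _resolve(traj.topology, selection)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selected atoms")
    ref = traj.frames[reference_frame, sel]
    _check_not_collinear(ref)
    ref_center = ref.mean(axis=0)
    ref_centered = ref - ref_center
    out = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        mobile = traj.frames[f, sel]
        center = mobile.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mobile - center)
        out[f] = rot.apply(traj.frames[f] - center) + ref_center
    return Trajectory(traj.topology, out, box=None, timestep=traj.timestep)


def rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection=None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (angstrom) to the reference after superposition."""
    sel = _resolve(traj.topology, selection)
    work = superpose(traj, reference_frame, selection) if fit else traj
    ref = work.frames[reference_frame, sel]
    diff = work.frames[:, sel] - ref
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))


def rmsf_profile(
    traj: Trajectory,
    selection=None,
    by_residue: bool = False,
) -> RMSFProfile:
    """Per-atom RMSF about the time-mean position.

    The trajectory is assumed already superposed.  With ``by_residue``
    the profile is reduced per residue using the CA atom when present,
    otherwise the unweighted mean over the residue's selected atoms.
    """
    sel = _resolve(traj.topology, selection)
    coords = traj.frames[:, sel]
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    if not by_residue:
        labels = [traj.topology.atoms[i].serial for i in sel]
        return RMSFProfile(labels, per_atom, "atoms", traj.n_frames, False)
    residues = traj.topology.residues
    sel_set = {int(i): p for i, p in zip(sel, range(len(sel)))}
    labels, values = [], []
    for res in residues:
        in_sel = [i for i in res.atom_indices if i in sel_set]
        if not in_sel:
            continue
        ca = [i for i in in_sel if traj.topology.atoms[i].name == "CA"]
        chosen = ca if ca else in_sel
        labels.append((res.chain, res.residue_id))
        values.append(np.mean([per_atom[sel_set[i]] for i in chosen]))
    return RMSFProfile(labels, np.array(values), "residues", traj.n_frames, True)


def rmsf_difference(a: RMSFProfile, b: RMSFProfile) -> dict:
    """Per-label differences ``b - a`` (sign convention mutant - wildtype)."""
    if a.labels != b.labels:
        raise ValueError("RMSF profiles have mismatched labels")
    return {label: float(vb - va) for label, va, vb in zip(a.labels, a.values, b.values)}


def cross_correlation(traj: Trajectory, selection=None) -> CorrelationMatrix:
    """Normalized cross-correlation C_ij of positional fluctuations.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the
    deviation from the time-mean position; diagonal is exactly 1.
    """
    if traj.n_frames < 2:
        raise ValueError("cross-correlation needs at least 2 frames")
    sel = _resolve(traj.topology, selection)
    coords = traj.frames[:, sel]
    delta = coords - coords.mean(axis=0)
    # inner products <dr_i . dr_j>: (n, n)
    dots = np.einsum("fid,fjd->ij", delta, delta) / traj.n_frames
    norms = np.sqrt(np.diag(dots))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = dots / np.outer(norms, norms)
    c[np.isnan(c)] = 0.0
    np.fill_diagonal(c, 1.0)
    labels = [traj.topology.atoms[i].serial for i in sel]
    return CorrelationMatrix(matrix=np.clip(c, -1.0, 1.0), labels=labels, selection="atoms")


def hbond_occupancy(
    traj: Trajectory,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    d_cut: float = 3.0,
    angle_cut: float = 135.0,
) -> list[HBond]:
    """Geometric hydrogen-bond occupancy over the trajectory.

    ``donors`` are (donor, hydrogen) atom-index pairs; ``acceptors`` are
    acceptor atom indices.  A bond is present in a frame when the
    donor-acceptor distance is <= ``d_cut`` (angstrom, heavy atoms) and
    the donor-hydrogen-acceptor angle is >= ``angle_cut`` (degrees).
    Distances honor the minimum-image convention when a box is present;
    angles use the local unwrapped geometry.
    """
    donors = [(int(d), int(h)) for d, h in donors]
    acceptors = [int(a) for a in acceptors]
    bonds = []
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            present = 0
            for f in range(traj.n_frames):
                frame = traj.frames[f]
                box = traj.box[f] if traj.box is not None else None
                da = minimum_image(frame[a] - frame[d], box)
                if np.linalg.norm(da) > d_cut:
                    continue
                hd = frame[d] - frame[h]
                ha = frame[a] - frame[h]
                cosang = np.dot(hd, ha) / (
                    np.linalg.norm(hd) * np.linalg.norm(ha) + 1e-300
                )
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= angle_cut:
                    present += 1
            bonds.append(HBond(d, h, a, present / traj.n_frames))
    return bonds


def filter_hbonds(bonds: Sequence[HBond], min_occupancy: float = 0.30) -> list[HBond]:
    """Bonds present in more than ``min_occupancy`` of frames (default 30%)."""
    return [b for b in bonds if b.occupancy > min_occupancy]
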