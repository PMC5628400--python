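"""Shared data model: atoms, molecular systems, trajectories, scalar grids.

Units are Cartesian angstroms for coordinates, kcal/mol for energies,
elementary charges for partial charges and kelvin for temperatures
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "MolecularSystem",
    "Trajectory",
    "ScalarGrid",
    "minimum_image",
]


@dataclass
class Atom:
    """A single atom with optional nonbonded parameters.

    ``vdw_radius`` (angstrom) is used by the hard-sphere tunnel search;
    ``charge`` (e), ``lj_sigma`` (angstrom) and ``lj_epsilon`` (kcal/mol)
    feed the pairwise energy decomposition.
    """

    serial: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain: str
    position: np.ndarray
    vdw_radius: float | None = None
    charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None
    insertion_code: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.serial}: position must be a 3-vector")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")
        if self.lj_epsilon is not None and self.lj_epsilon < 0:
            raise ValueError(f"atom {self.serial}: lj_epsilon must be >= 0")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_id, self.insertion_code)


@dataclass(frozen=True)
class Residue:
    """A contiguous group of atoms sharing (chain, residue_id, icode)."""

    chain: str
    residue_id: int
    name: str
    atom_indices: tuple[int, ...]
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_id, self.insertion_code)

    def __len__(self) -> int:
        return len(self.atom_indices)


class MolecularSystem:
    """An ordered atom list with residue grouping and nonbonded bookkeeping.

    ``exclusions`` holds unordered 0-based atom-index pairs whose nonbonded
    interaction is skipped entirely; ``scaled14`` maps unordered pairs to
    (coulomb_scale, lj_scale) factors.  A pair may not appear in both.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        exclusions: Iterable[tuple[int, int]] = (),
        scaled14: Mapping[tuple[int, int], tuple[float, float]] | None = None,
    ) -> None:
        self.atoms: list[Atom] = list(atoms)
        self.exclusions: set[tuple[int, int]] = {
            tuple(sorted(p)) for p in exclusions  # type: ignore[misc]
        }
        self.scaled14: dict[tuple[int, int], tuple[float, float]] = {
            tuple(sorted(k)): tuple(v)  # type: ignore[misc]
            for k, v in (scaled14 or {}).items()
        }
        overlap = self.exclusions & set(self.scaled14)
        if overlap:
            raise ValueError(f"pairs both excluded and scaled-1-4: {sorted(overlap)}")
        self._residues: list[Residue] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    @coordinates.setter
    def coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected shape ({self.n_atoms}, 3), got {coords.shape}")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    @property
    def residues(self) -> list[Residue]:
        if self._residues is None:
            self._residues = self._group_residues()
        return self._residues

    def _group_residues(self) -> list[Residue]:
        residues: list[Residue] = []
        current: list[int] = []
        key: tuple[str, int, str] | None = None
        name = ""
        for i, atom in enumerate(self.atoms):
            if atom.residue_key != key:
                if current:
                    residues.append(
                        Residue(key[0], key[1], name, tuple(current), key[2])
                    )
                key = atom.residue_key
                name = atom.residue_name
                current = []
            current.append(i)
        if current:
            residues.append(Residue(key[0], key[1], name, tuple(current), key[2]))
        assert sum(len(r) for r in residues) == self.n_atoms
        return residues

    def residue_of_atom(self, atom_index: int) -> int:
        """Index into ``self.residues`` of the residue owning an atom."""
        for ri, res in enumerate(self.residues):
            if atom_index in res.atom_indices:
                return ri
        raise IndexError(f"atom index {atom_index} out of range")

    def find_residue(self, residue_id: int, chain: str | None = None) -> int:
        matches = [
            i
            for i, r in enumerate(self.residues)
            if r.residue_id == residue_id and (chain is None or r.chain == chain)
        ]
        if not matches:
            raise KeyError(f"no residue with id {residue_id}" + (f" in chain {chain}" if chain else ""))
        if len(matches) > 1:
            raise KeyError(f"residue id {residue_id} is ambiguous; pass chain")
        return matches[0]

    def select(
        self,
        name: str | Iterable[str] | None = None,
        resname: str | Iterable[str] | None = None,
        element: str | Iterable[str] | None = None,
        chain: str | Iterable[str] | None = None,
        serials: Iterable[int] | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria (AND semantics)."""

        def as_set(v):
            if v is None:
                return None
            return {v} if isinstance(v, str) else set(v)

        names, resnames = as_set(name), as_set(resname)
        elements, chains = as_set(element), as_set(chain)
        serial_set = set(serials) if serials is not None else None
        out = []
        for i, a in enumerate(self.atoms):
            if names is not None and a.name not in names:
                continue
            if resnames is not None and a.residue_name not in resnames:
                continue
            if elements is not None and a.element not in elements:
                continue
            if chains is not None and a.chain not in chains:
                continue
            if serial_set is not None and a.serial not in serial_set:
                continue
            out.append(i)
        return np.array(out, dtype=int)


class Trajectory:
    """Frames of coordinates over a fixed topology.

    ``frames`` is (n_frames, n_atoms, 3) in angstrom; ``box`` holds optional
    per-frame orthorhombic box edge lengths (n_frames, 3); ``timestep`` is
    ps per frame when known.
    """

    def __init__(
        self,
        topology: MolecularSystem,
        frames: np.ndarray | Sequence[np.ndarray],
        box: np.ndarray | None = None,
        timestep: float | None = None,
    ) -> None:
        frames = np.asarray(frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3 or frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if frames.shape[1] != topology.n_atoms:
            raise ValueError(
                f"frame atom count {frames.shape[1]} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        self.topology = topology
        self.frames = frames
        if box is not None:
            box = np.asarray(box, dtype=float)
            if box.ndim == 1:
                box = np.tile(box, (len(frames), 1))
            if box.shape != (len(frames), 3):
                raise ValueError("box must have shape (n_frames, 3)")
            if np.any(box <= 0):
                raise ValueError("box lengths must be > 0")
        self.box = box
        self.timestep = timestep

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def frame_system(self, index: int) -> MolecularSystem:
        """A copy-free view is impossible with per-atom positions; return the
        topology with coordinates set to the requested frame."""
        self.topology.coordinates = self.frames[index]
        return self.topology


@dataclass
class ScalarGrid:
    """A regular 3D scalar field with uniform voxel spacing."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel center coordinates."""
        axes = [
            self.origin[d] + self.spacing * np.arange(self.shape[d])
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def index_of(self, point: np.ndarray) -> tuple[int, int, int]:
        """Index of the voxel whose center is nearest the point."""
        idx = np.round((np.asarray(point, float) - self.origin) / self.spacing)
        idx = idx.astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.shape)):
            raise IndexError(f"point {point} outside grid")
        return tuple(idx)

    def center_of(self, index: Sequence[int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(index, dtype=float)


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` is (..., 3); ``box`` is per-frame orthorhombic edge lengths
    broadcastable against it, or None for a non-periodic system.
    """
    delta = np.asarray(delta, dtype=float)
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)
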