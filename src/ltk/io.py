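"""Structure, trajectory, parameter-table and grid file I/O.

PDB reading is deliberately strict about the fixed-column coordinate
fields so that malformed records are reported with their line number —
downstream analyses silently misbehave on half-parsed structures.
Binary trajectories use the DCD dialect through MDAnalysis; OpenDX
scalar grids go through gridDataFormats so the output loads in VMD and
PyMOL unchanged.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import Atom, MolecularSystem, ScalarGrid, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "PDBParseError",
    "BONDI_RADII",
    "read_structure",
    "write_structure",
    "assign_vdw_radii",
    "read_trajectory",
    "write_trajectory",
    "read_nonbonded_params",
    "write_density_dx",
    "read_density_dx",
]


class PDBParseError(ValueError):
    """Raised when a PDB record cannot be parsed; carries the line number."""


#: Bondi (1964) van der Waals radii in angstrom, the de-facto standard
#: hard-sphere radii for steric tunnel analysis.  Elements missing from
#: Bondi's table (metals commonly seen in metalloenzyme structures) carry
#: widely used supplementary values.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "HE": 1.40,
    "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "NE": 1.54,
    "SI": 2.10, "P": 1.80, "S": 1.80, "CL": 1.75, "AR": 1.88,
    "BR": 1.85, "I": 1.98, "KR": 2.02, "XE": 2.16,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "CU": 1.40,
    "FE": 1.95, "MN": 1.95, "CA": 2.31, "NI": 1.63,
}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if len(stripped) >= 2 and stripped[:2].upper() in BONDI_RADII and stripped[:2].isalpha():
        # Two-letter element only when the PDB name starts with it and the
        # second char is lower case (e.g. "Fe", "Cl"); all-caps protein
        # names like "CA"/"CD" are carbons.
        if stripped[1].islower():
            return stripped[:2].upper()
    return stripped[0].upper()


def _parse_atom_record(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad atom serial {line[6:11]!r}") from exc
    name = line[12:16].strip()
    resname = line[17:20].strip()
    chain = line[21:22].strip()
    try:
        resid = int(line[22:26])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from exc
    icode = line[26:27].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(
            f"line {lineno}: malformed coordinate field in {line[30:54]!r}"
        ) from exc
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_id=resid,
        residue_name=resname,
        chain=chain,
        position=np.array([x, y, z]),
        insertion_code=icode,
    )


def _parse_pdb_models(path: str | Path) -> list[list[Atom]]:
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                if current:
                    models.append(current)
                    current = []
                in_model = True
            elif record == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif record in ("ATOM", "HETATM"):
                current.append(_parse_atom_record(line, lineno))
    if current or not models:
        if current:
            models.append(current)
    # drop empty models produced by stray MODEL/ENDMDL pairs
    models = [m for m in models if m]
    return models


def read_structure(path: str | Path) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem`.

    Multi-model files return the first model only (use
    :func:`read_trajectory` for the full ensemble).  Atoms keep file
    order; residues are grouped by chain, residue number and insertion
    code.
    """
    models = _parse_pdb_models(path)
    if not models:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return MolecularSystem(models[0])


def _format_atom_line(atom: Atom, serial: int, position: np.ndarray) -> str:
    name = atom.name
    # PDB alignment rule: 1-3 char names start in column 14 unless they
    # begin with a 2-letter element symbol.
    if len(name) < 4 and len(atom.element) < 2:
        name = f" {name}"
    return (
        f"HETATM{serial:>5d} {name:<4.4s}{atom.residue_name[:3]:>4.3s} "
        f"{atom.chain[:1]:1.1s}{atom.residue_id:>4d}{atom.insertion_code:1.1s}   "
        f"{position[0]:8.3f}{position[1]:8.3f}{position[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {atom.element:>2.2s}\n"
    )


def write_structure(system: MolecularSystem, path: str | Path) -> None:
    """Write a single-model PDB file (HETATM records, file atom order)."""
    with open(path, "w") as fh:
        for i, atom in enumerate(system.atoms):
            fh.write(_format_atom_line(atom, (i + 1) % 100000, atom.position))
        fh.write("END\n")


def assign_vdw_radii(
    system: MolecularSystem,
    table: Mapping[str, float] | None = None,
    default: float | None = None,
) -> MolecularSystem:
    """Assign per-atom van der Waals radii from an element->radius table.

    The packaged default is the Bondi table.  Elements absent from the
    table fall back to ``default`` (with a logged warning); if no default
    is given, unknown elements raise an error listing the offending atoms.
    Returns the same system, mutated, for chaining.
    """
    table = {k.upper(): v for k, v in (table or BONDI_RADII).items()}
    unknown: list[Atom] = []
    for atom in system.atoms:
        radius = table.get(atom.element.upper())
        if radius is None:
            if default is None:
                unknown.append(atom)
                continue
            logger.warning(
                "element %r of atom %d not in radius table; using default %.2f",
                atom.element, atom.serial, default,
            )
            warnings.warn(
                f"element {atom.element!r} (atom {atom.serial}) not in radius "
                f"table; using default {default}",
                stacklevel=2,
            )
            radius = default
        atom.vdw_radius = float(radius)
    if unknown:
        desc = ", ".join(f"{a.serial}:{a.element or '?'}" for a in unknown[:10])
        raise KeyError(
            f"{len(unknown)} atoms have elements missing from the radius "
            f"table and no default was given: {desc}"
        )
    return system


def _read_dcd_frames(path: str | Path, n_atoms: int) -> tuple[np.ndarray, np.ndarray | None]:
    from MDAnalysis.coordinates.DCD import DCDReader

    reader = DCDReader(str(path))
    frames = []
    boxes = []
    has_box = False
    for ts in reader:
        if ts.positions.shape[0] != n_atoms:
            raise ValueError(
                f"{path}: expected {n_atoms} atoms per frame, found {ts.positions.shape[0]}"
            )
        frames.append(ts.positions.astype(float).copy())
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            has_box = True
            boxes.append(ts.dimensions[:3].astype(float).copy())
        else:
            boxes.append(np.zeros(3))
    reader.close()
    return np.array(frames), (np.array(boxes) if has_box else None)


def read_trajectory(
    paths: str | Path | Sequence[str | Path],
    topology: MolecularSystem,
) -> Trajectory:
    """Read one or more trajectory files (multi-model PDB or DCD).

    Frames are concatenated across files in argument order; every frame
    must match the topology's atom count.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    all_frames: list[np.ndarray] = []
    all_boxes: list[np.ndarray] | None = []
    for path in paths:
        path = Path(path)
        if path.suffix.lower() == ".dcd":
            frames, boxes = _read_dcd_frames(path, topology.n_atoms)
        else:
            models = _parse_pdb_models(path)
            for m in models:
                if len(m) != topology.n_atoms:
                    raise ValueError(
                        f"{path}: expected {topology.n_atoms} atoms per model, "
                        f"found {len(m)}"
                    )
            frames = np.array([[a.position for a in m] for m in models])
            boxes = None
        all_frames.append(frames)
        if boxes is None:
            all_boxes = None
        elif all_boxes is not None:
            all_boxes.append(boxes)
    frames = np.concatenate(all_frames, axis=0)
    box = np.concatenate(all_boxes, axis=0) if all_boxes else None
    return Trajectory(topology, frames, box=box)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB or DCD (chosen by suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        import MDAnalysis as mda
        from MDAnalysis.coordinates.DCD import DCDWriter

        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with DCDWriter(str(path), traj.n_atoms) as writer:
                for i in range(traj.n_frames):
                    u.atoms.positions = traj.frames[i]
                    if traj.box is not None:
                        u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
                    writer.write(u.atoms)
        return
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"MODEL {i + 1:>8d}\n")
            for j, atom in enumerate(traj.topology.atoms):
                fh.write(_format_atom_line(atom, (j + 1) % 100000, traj.frames[i, j]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _iter_param_rows(path: str | Path):
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1].strip().lower()
                continue
            yield lineno, section, line.split()


def read_nonbonded_params(
    path: str | Path,
    system: MolecularSystem,
    permissive: bool = False,
) -> MolecularSystem:
    """Load charges, LJ parameters, exclusions and scaled-1-4 pairs.

    The file is whitespace/tab-separated with ``[charges]``, ``[lj]``,
    ``[exclusions]`` and ``[scaled14]`` sections; rows are keyed by atom
    serial.  Unless ``permissive`` is set, every atom must receive a
    charge and LJ parameters.
    """
    serial_to_index = {}
    for i, atom in enumerate(system.atoms):
        if atom.serial in serial_to_index:
            raise ValueError(f"system has duplicate atom serial {atom.serial}")
        serial_to_index[atom.serial] = i

    def index_for(serial_text: str, lineno: int) -> int:
        serial = int(serial_text)
        if serial not in serial_to_index:
            raise ValueError(f"line {lineno}: atom serial {serial} not in system")
        return serial_to_index[serial]

    seen_charge: set[int] = set()
    seen_lj: set[int] = set()
    exclusions: set[tuple[int, int]] = set()
    scaled14: dict[tuple[int, int], tuple[float, float]] = {}
    for lineno, section, fields in _iter_param_rows(path):
        if section == "charges":
            idx = index_for(fields[0], lineno)
            if idx in seen_charge:
                raise ValueError(f"line {lineno}: duplicate charge for serial {fields[0]}")
            system.atoms[idx].charge = float(fields[1])
            seen_charge.add(idx)
        elif section == "lj":
            idx = index_for(fields[0], lineno)
            if idx in seen_lj:
                raise ValueError(f"line {lineno}: duplicate LJ row for serial {fields[0]}")
            system.atoms[idx].lj_sigma = float(fields[1])
            system.atoms[idx].lj_epsilon = float(fields[2])
            seen_lj.add(idx)
        elif section == "exclusions":
            i, j = index_for(fields[0], lineno), index_for(fields[1], lineno)
            exclusions.add(tuple(sorted((i, j))))
        elif section == "scaled14":
            i, j = index_for(fields[0], lineno), index_for(fields[1], lineno)
            # AMBER conventions when factors omitted: 1/1.2 Coulomb, 1/2 LJ
            cs = float(fields[2]) if len(fields) > 2 else 1.0 / 1.2
            ls = float(fields[3]) if len(fields) > 3 else 0.5
            scaled14[tuple(sorted((i, j)))] = (cs, ls)
        else:
            raise ValueError(f"line {lineno}: row outside a recognized section")
    if not permissive:
        missing = [
            a.serial for a in system.atoms if a.charge is None or a.lj_sigma is None
        ]
        if missing:
            raise ValueError(
                f"atoms without full nonbonded parameters: serials {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
    system.exclusions |= exclusions
    overlap = system.exclusions & set(scaled14)
    if overlap:
        raise ValueError(f"pairs both excluded and scaled-1-4: {sorted(overlap)}")
    system.scaled14.update(scaled14)
    return system


def write_density_dx(grid: ScalarGrid, path: str | Path) -> None:
    """Write a scalar grid as an OpenDX field readable by VMD/PyMOL."""
    from gridData import Grid

    if not np.all(np.isfinite(grid.values)):
        raise ValueError("grid contains non-finite values; refusing to write DX")
    g = Grid(
        grid.values,
        origin=grid.origin.astype(float),
        delta=[grid.spacing] * 3,
    )
    g.export(str(path), file_format="dx")


def read_density_dx(path: str | Path) -> ScalarGrid:
    """Read an OpenDX scalar field written by :func:`write_density_dx`."""
    from gridData import Grid

    g = Grid(str(path))
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        delta = np.diag(delta)
    if not np.allclose(delta, delta[0]):
        raise ValueError(f"{path}: anisotropic grid spacing not supported")
    return ScalarGrid(origin=np.asarray(g.origin, float), spacing=float(delta[0]), values=np.asarray(g.grid, float))
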