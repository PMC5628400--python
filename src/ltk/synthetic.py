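"""Synthetic input generators with known ground truth.

Every generator here replaces one class of inputs the analysis modules
expect from molecular-dynamics simulations of an O2-transporting enzyme:

* :func:`make_channel_system` — a protein-like atom cloud with an embedded
  cylindrical channel of known inner radius, enclosed by an atom shell so
  the only path from the channel midpoint to the exterior runs through an
  open cap.  Exercises the tunnel search with an analytically known answer.
* :func:`simulate_umbrella_windows` — biased reaction-coordinate samples
  drawn by Metropolis Monte Carlo from exp(-[F(x)+U_bias(x)]/kT) for a
  stated true free-energy profile F.  Exercises WHAM recovery.
* :func:`simulate_ligand_diffusion` — ligand trajectories with scripted
  entrance/exit events; the returned event log is the exact truth table
  for the entrance detector.
* :func:`make_fluctuation_trajectory` — i.i.d. multivariate-Gaussian
  positional fluctuations with stated variances and pair correlations, the
  closed-form oracle for RMSF and cross-correlation analysis.
* :func:`make_point_charge_system` — small point-charge/LJ systems with
  analytically computable pair energies for the energy decomposition.

All generators are bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import Atom, MolecularSystem, Trajectory

__all__ = [
    "KB_KCAL",
    "ChannelSpec",
    "PMFSpec",
    "DiffusionSpec",
    "make_channel_system",
    "simulate_umbrella_windows",
    "simulate_ligand_diffusion",
    "make_fluctuation_trajectory",
    "make_point_charge_system",
]

#: Boltzmann constant in kcal/(mol K), the value used by the standard
#: umbrella-sampling WHAM codes.
KB_KCAL = 0.0019872041


# ---------------------------------------------------------------------------
# channel geometry


@dataclass
class ChannelSpec:
    """Geometry of a synthetic cylindrical channel embedded in an atom shell.

    The channel wall is a tube of hard-sphere atoms of radius
    ``wall_atom_radius`` whose centers sit at ``inner_radius +
    wall_atom_radius`` from the axis, so the free radius on the axis equals
    ``inner_radius``.  ``cap_open`` controls which ends connect to the
    exterior of the enclosing shell.
    """

    inner_radius: float = 3.0
    length: float = 20.0
    wall_atom_radius: float = 1.5
    wall_atom_spacing: float = 0.8
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    cap_open: tuple[bool, bool] = (True, False)

    def __post_init__(self) -> None:
        if self.wall_atom_radius <= 0:
            raise ValueError("wall_atom_radius must be > 0")
        if self.inner_radius <= self.wall_atom_radius:
            raise ValueError("inner_radius must exceed wall_atom_radius")
        if self.wall_atom_spacing >= self.wall_atom_radius:
            raise ValueError(
                "wall_atom_spacing must be smaller than wall_atom_radius "
                "(dense, leak-free wall)"
            )
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            raise ValueError("degenerate channel axis")
        self.axis = tuple(axis / norm)


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def _tube_points(
    axis: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    s_values: np.ndarray,
    ring_radius: float,
    spacing: float,
) -> list[np.ndarray]:
    pts = []
    n_ang = max(6, int(np.ceil(2 * np.pi * ring_radius / spacing)))
    for k, s in enumerate(s_values):
        offset = (k % 2) * np.pi / n_ang  # stagger rings to close gaps
        ang = offset + 2 * np.pi * np.arange(n_ang) / n_ang
        ring = (
            s * axis
            + ring_radius * np.outer(np.cos(ang), e1)
            + ring_radius * np.outer(np.sin(ang), e2)
        )
        pts.extend(ring)
    return pts


def _disk_points(
    center: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    max_radius: float,
    spacing: float,
) -> list[np.ndarray]:
    pts = [center.copy()]
    for rho in np.arange(spacing, max_radius + spacing / 2, spacing):
        n_ang = max(6, int(np.ceil(2 * np.pi * rho / spacing)))
        ang = 2 * np.pi * np.arange(n_ang) / n_ang
        pts.extend(center + rho * np.outer(np.cos(ang), e1) + rho * np.outer(np.sin(ang), e2))
    return pts


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def make_channel_system(spec: ChannelSpec, seed: int = 0) -> MolecularSystem:
    """Build the channel-in-shell test system.

    The tube runs from -length/2 to +length/2 along the axis.  Open ends
    are extended through a hole in the enclosing quasi-random spherical
    shell; closed ends are sealed with an atom disk, so a grid search from
    the axis midpoint reaches the exterior only through open caps.
    """
    axis = np.asarray(spec.axis, dtype=float)
    e1, e2 = _orthonormal_frame(axis)
    ring_radius = spec.inner_radius + spec.wall_atom_radius
    half = spec.length / 2
    shell_radius = float(np.hypot(half, ring_radius)) + 5.0

    pts: list[np.ndarray] = []
    # main tube
    s_main = np.arange(-half, half + spec.wall_atom_spacing / 2, spec.wall_atom_spacing)
    pts.extend(_tube_points(axis, e1, e2, s_main, ring_radius, spec.wall_atom_spacing))
    for end, sign in zip(spec.cap_open, (-1.0, 1.0)):
        if end:
            # extend the tube through the shell so the mouth opens outside
            s_ext = np.arange(
                half + spec.wall_atom_spacing,
                shell_radius + 2.0,
                spec.wall_atom_spacing,
            )
            pts.extend(_tube_points(axis, e1, e2, sign * s_ext, ring_radius, spec.wall_atom_spacing))
        else:
            pts.extend(
                _disk_points(sign * half * axis, e1, e2, ring_radius, spec.wall_atom_spacing)
            )

    # enclosing shell with holes where open tubes pass through
    shell_spacing = 2.0 * spec.wall_atom_radius * 0.8
    n_shell = int(np.ceil(4 * np.pi * shell_radius**2 / shell_spacing**2 * 2.0))
    rng = np.random.default_rng(seed)
    directions = _fibonacci_sphere(n_shell)
    jitter = rng.normal(scale=0.05 * shell_spacing, size=directions.shape)
    shell = shell_radius * directions + jitter
    axial = shell @ axis
    perp = np.linalg.norm(shell - np.outer(axial, axis), axis=1)
    keep = np.ones(len(shell), dtype=bool)
    for end, sign in zip(spec.cap_open, (-1.0, 1.0)):
        if end:
            keep &= ~((np.sign(axial) == sign) & (perp < ring_radius))
    pts.extend(shell[keep])

    atoms = [
        Atom(
            serial=i + 1,
            name="C",
            element="C",
            residue_id=i + 1,
            residue_name="WAL",
            chain="A",
            position=p,
            vdw_radius=spec.wall_atom_radius,
        )
        for i, p in enumerate(pts)
    ]
    return MolecularSystem(atoms)


# ---------------------------------------------------------------------------
# umbrella-sampling windows


_PMF_FORMS: dict[str, Callable[[np.ndarray, Mapping[str, float]], np.ndarray]] = {
    "constant": lambda x, p: np.full_like(x, p.get("value", 0.0)),
    "linear": lambda x, p: p.get("slope", 1.0) * x + p.get("intercept", 0.0),
    "harmonic": lambda x, p: p.get("a", 1.0) * (x - p.get("x0", 0.0)) ** 2,
    "double_well": lambda x, p: p.get("a", 1.0) * (x**2 - p.get("b", 1.0) ** 2) ** 2,
}


@dataclass
class PMFSpec:
    """A true free-energy profile F(x) in kcal/mol on [x_min, x_max].

    Supported forms: ``constant`` (value), ``linear`` (slope, intercept),
    ``harmonic`` (a, x0: a*(x-x0)^2) and ``double_well`` (a, b:
    a*(x^2-b^2)^2, barrier height a*b^4 between wells at +-b).
    """

    form: str
    params: dict[str, float] = field(default_factory=dict)
    x_range: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        if self.form not in _PMF_FORMS:
            raise ValueError(
                f"unknown PMF form {self.form!r}; choose from {sorted(_PMF_FORMS)}"
            )
        if not self.x_range[0] < self.x_range[1]:
            raise ValueError("x_range must be increasing")
        if not np.all(np.isfinite(self(np.linspace(*self.x_range, 101)))):
            raise ValueError("F must be finite on x_range")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return _PMF_FORMS[self.form](np.asarray(x, dtype=float), self.params)


def simulate_umbrella_windows(
    pmf: PMFSpec,
    centers: Sequence[float],
    k: float,
    n_samples: int,
    temperature: float = 300.0,
    seed: int = 0,
    bias_convention: str = "full",
    proposal_width: float = 0.2,
    burn_in: int = 1000,
    stride: int = 10,
    n_walkers: int | None = None,
):
    """Draw biased samples per window by Metropolis Monte Carlo.

    The biased density in window i is proportional to
    exp(-[F(x) + U_bias(x)] / kT) with U_bias = k (x - x0)^2 for the
    ``full`` convention (the AMBER restraint form) or (1/2) k (x - x0)^2
    for ``half`` (the Grossfield-WHAM default).  Sampling runs many
    independent walkers in parallel, each with its own burn-in and a
    fixed stride between retained samples.

    Returns a list of :class:`ltk.wham.UmbrellaWindow`.
    """
    from .wham import UmbrellaWindow, bias_factor

    if k <= 0:
        raise ValueError("force constant k must be > 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    centers = np.asarray(centers, dtype=float)
    lo, hi = pmf.x_range
    if np.any(centers < lo) or np.any(centers > hi):
        bad = centers[(centers < lo) | (centers > hi)]
        raise ValueError(f"window centers outside [{lo}, {hi}]: {bad}")
    conv = bias_factor(bias_convention)
    kt = KB_KCAL * temperature

    rng = np.random.default_rng(seed)
    windows = []
    for x0 in centers:
        if n_walkers is None:
            walkers = int(np.clip(n_samples // 64, 1, 256))
        else:
            walkers = n_walkers
        per_walker = int(np.ceil(n_samples / walkers))

        def energy(x: np.ndarray) -> np.ndarray:
            e = pmf(x) + conv * k * (x - x0) ** 2
            return np.where((x < lo) | (x > hi), np.inf, e)

        x = np.full(walkers, x0) + rng.normal(scale=0.05, size=walkers)
        x = np.clip(x, lo, hi)
        e = energy(x)
        kept = np.empty((per_walker, walkers))
        n_steps = burn_in + per_walker * stride
        for step in range(n_steps):
            prop = x + rng.normal(scale=proposal_width, size=walkers)
            e_prop = energy(prop)
            accept = rng.random(walkers) < np.exp(np.minimum(0.0, -(e_prop - e) / kt))
            x = np.where(accept, prop, x)
            e = np.where(accept, e_prop, e)
            if step >= burn_in and (step - burn_in) % stride == stride - 1:
                kept[(step - burn_in) // stride] = x
        samples = kept.T.reshape(-1)[:n_samples]
        windows.append(
            UmbrellaWindow(
                samples=samples,
                center=float(x0),
                force_constant=float(k),
                bias_convention=bias_convention,
                temperature=float(temperature),
            )
        )
    return windows


# ---------------------------------------------------------------------------
# ligand diffusion with scripted events


@dataclass
class DiffusionSpec:
    """Scripted ligand entrance/exit events around a binding site.

    ``events[ligand_id]`` is a list of (entry_frame, exit_frame) pairs,
    inclusive at both ends and disjoint per ligand.  During an event the
    ligand centroid stays at least 1 A inside ``entrance_threshold``;
    outside events it stays at least 1 A beyond it, so threshold-based
    detection recovers the script exactly.
    """

    site_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    entrance_threshold: float = 6.0
    events: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    step: float = 0.5

    def __post_init__(self) -> None:
        for lig, evs in self.events.items():
            evs = sorted(evs)
            for entry, exit_ in evs:
                if entry >= exit_:
                    raise ValueError(
                        f"ligand {lig}: entry_frame {entry} must precede exit_frame {exit_}"
                    )
            for (_, e0), (s1, _) in zip(evs, evs[1:]):
                if s1 <= e0:
                    raise ValueError(f"ligand {lig}: overlapping events")
            self.events[lig] = evs


def simulate_ligand_diffusion(
    spec: DiffusionSpec,
    n_ligands: int,
    n_frames: int,
    seed: int = 0,
) -> tuple[Trajectory, list[tuple[int, int, int]]]:
    """Generate a flooding-style trajectory with scripted entrances.

    The topology holds one fixed site atom (FE, residue 1) followed by
    diatomic O2 ligands (residues OXY).  Returns the trajectory and the
    ground-truth event log as (ligand_id, entry_frame, exit_frame) with
    ligand_id numbered from 0.
    """
    for lig, evs in spec.events.items():
        if lig >= n_ligands:
            raise ValueError(f"event scripted for ligand {lig} but only {n_ligands} ligands")
        if evs and evs[-1][1] >= n_frames:
            raise ValueError(
                f"ligand {lig}: event ending at frame {evs[-1][1]} exceeds n_frames={n_frames}"
            )
    rng = np.random.default_rng(seed)
    site = np.asarray(spec.site_center, dtype=float)
    thr = spec.entrance_threshold
    inner_max = thr - 1.2  # stay clearly inside during events
    outer_min = thr + 1.2  # stay clearly outside otherwise

    atoms = [
        Atom(1, "FE", "FE", 1, "SIT", "A", site.copy()),
    ]
    for lig in range(n_ligands):
        for j in (1, 2):
            atoms.append(
                Atom(
                    serial=2 + 2 * lig + (j - 1),
                    name=f"O{j}",
                    element="O",
                    residue_id=2 + lig,
                    residue_name="OXY",
                    chain="B",
                    position=np.zeros(3),
                )
            )
    topology = MolecularSystem(atoms)

    frames = np.zeros((n_frames, len(atoms), 3))
    frames[:, 0] = site
    half_bond = 1.21 / 2  # O2 bond length

    for lig in range(n_ligands):
        inside = np.zeros(n_frames, dtype=bool)
        for entry, exit_ in spec.events.get(lig, []):
            inside[entry : exit_ + 1] = True
        # random-walk radial distance within the allowed band per frame
        r = np.empty(n_frames)
        r[0] = inner_max / 2 if inside[0] else outer_min + 6.0
        for t in range(1, n_frames):
            lo_band, hi_band = (
                (1.0, inner_max) if inside[t] else (outer_min, outer_min + 15.0)
            )
            prev = r[t - 1] if (inside[t] == inside[t - 1]) else (lo_band + hi_band) / 2
            r[t] = np.clip(prev + rng.normal(scale=spec.step), lo_band, hi_band)
        directions = _fibonacci_sphere(max(n_frames, 2))[:n_frames]
        directions = directions[rng.permutation(n_frames)]
        centroids = site + r[:, None] * directions
        orient = rng.normal(size=3)
        orient /= np.linalg.norm(orient)
        frames[:, 1 + 2 * lig] = centroids - half_bond * orient
        frames[:, 2 + 2 * lig] = centroids + half_bond * orient

    event_log = [
        (lig, entry, exit_)
        for lig in range(n_ligands)
        for entry, exit_ in spec.events.get(lig, [])
    ]
    return Trajectory(topology, frames), event_log


# ---------------------------------------------------------------------------
# Gaussian fluctuation ensembles


def make_fluctuation_trajectory(
    means: np.ndarray,
    stdevs: np.ndarray,
    pair_correlations: Mapping[tuple[int, int], float] | None = None,
    n_frames: int = 1000,
    seed: int = 0,
) -> Trajectory:
    """Draw i.i.d. multivariate-Gaussian frames about per-atom means.

    ``stdevs`` is (n_atoms, 3) per-axis standard deviations in angstrom;
    ``pair_correlations`` maps atom index pairs to a correlation
    coefficient applied on every axis.  The per-atom RMSF converges to
    sqrt(sum_axes stdev^2) and the normalized cross-correlation to the
    requested coefficients.
    """
    means = np.asarray(means, dtype=float).reshape(-1, 3)
    stdevs = np.asarray(stdevs, dtype=float).reshape(-1, 3)
    if means.shape != stdevs.shape:
        raise ValueError("means and stdevs must have matching shapes")
    if np.any(stdevs < 0):
        raise ValueError("stdevs must be >= 0")
    n = len(means)
    corr = np.eye(n)
    for (i, j), rho in (pair_correlations or {}).items():
        corr[i, j] = corr[j, i] = rho
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"correlation specification is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )
    # square root of the correlation matrix via eigendecomposition
    w, v = np.linalg.eigh(corr)
    sqrt_corr = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_frames, 3, n))
    correlated = z @ sqrt_corr.T  # (n_frames, 3, n)
    disp = correlated.transpose(0, 2, 1) * stdevs[None]
    frames = means[None] + disp

    atoms = [
        Atom(i + 1, "CA", "C", i + 1, "GLY", "A", means[i].copy())
        for i in range(n)
    ]
    return Trajectory(MolecularSystem(atoms), frames)


# ---------------------------------------------------------------------------
# point-charge / LJ oracle systems


def make_point_charge_system(
    positions: np.ndarray,
    charges: Sequence[float],
    lj_params: Sequence[tuple[float, float]] | None = None,
) -> MolecularSystem:
    """Build a system of single-atom residues with explicit q, sigma, eps.

    Each atom is its own residue, so every pair is an inter-residue pair
    and the energy decomposition equals the plain pairwise sum — the
    analytic oracle for the EDA module.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if len(positions) != len(charges):
        raise ValueError("positions and charges must be congruent")
    if lj_params is not None and len(lj_params) != len(positions):
        raise ValueError("lj_params must be congruent with positions")
    atoms = []
    for i, pos in enumerate(positions):
        sigma, eps = lj_params[i] if lj_params is not None else (1.0, 0.0)
        atoms.append(
            Atom(
                serial=i + 1,
                name="Q",
                element="X",
                residue_id=i + 1,
                residue_name="ION",
                chain="A",
                position=pos,
                charge=float(charges[i]),
                lj_sigma=float(sigma),
                lj_epsilon=float(eps),
            )
        )
    return MolecularSystem(atoms)
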