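"""Per-residue nonbonded energy decomposition (EDA).

For a target residue, the ensemble-averaged Coulomb and Lennard-Jones
interaction with every other residue is

    <dE_i> = < sum_{a in target, b in residue i} E_pair(a, b) >_frames

with E_Coul = C q_a q_b / r (C = 332.0636 kcal A / (mol e^2)) and
E_LJ = 4 eps_ab [(sigma_ab/r)^12 - (sigma_ab/r)^6] under Lorentz-Berthelot
combining (arithmetic sigma, geometric eps).  Excluded pairs are skipped,
scaled-1-4 pairs multiplied by their factors, and intra-residue pairs are
never counted — the decomposition is inter-residue by definition.  Plain
pairwise sums with no cutoff are the default (an optional cutoff is
provided); minimum-image displacements are used when the trajectory
carries a box.  Differences between variants (e.g. wild type vs. a point
mutant) combine uncertainties in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import Trajectory, minimum_image

__all__ = [
    "COULOMB_CONSTANT",
    "EDAResult",
    "residue_interaction_energies",
    "eda_total",
    "eda_difference",
]

#: Coulomb conversion constant in kcal*angstrom/(mol*e^2), the AMBER value.
COULOMB_CONSTANT = 332.0636


@dataclass
class EDAResult:
    """Per-partner-residue interaction energies with frame statistics.

    ``coul_frames``/``vdw_frames`` hold the per-frame per-partner sums,
    shape (n_frames, n_partners), from which means and standard errors
    are derived; keeping them allows the total's SEM to be computed from
    per-frame totals rather than by (incorrectly) summing partner SEMs.
    """

    target_key: tuple[str, int]
    partner_keys: list[tuple[str, int]]
    partner_names: list[str]
    coul_frames: np.ndarray
    vdw_frames: np.ndarray

    def __post_init__(self) -> None:
        self.coul_frames = np.atleast_2d(np.asarray(self.coul_frames, float))
        self.vdw_frames = np.atleast_2d(np.asarray(self.vdw_frames, float))
        if self.coul_frames.shape != self.vdw_frames.shape:
            raise ValueError("coulomb and vdw frame arrays must be congruent")
        if self.coul_frames.shape[1] != len(self.partner_keys):
            raise ValueError("frame arrays must have one column per partner")

    @property
    def n_frames(self) -> int:
        return self.coul_frames.shape[0]

    @property
    def mean_coul(self) -> np.ndarray:
        return self.coul_frames.mean(axis=0)

    @property
    def mean_vdw(self) -> np.ndarray:
        return self.vdw_frames.mean(axis=0)

    @property
    def mean_total(self) -> np.ndarray:
        return self.mean_coul + self.mean_vdw

    def _sem(self, frames: np.ndarray) -> np.ndarray:
        if self.n_frames < 2:
            return np.zeros(frames.shape[1])
        return frames.std(axis=0, ddof=1) / np.sqrt(self.n_frames)

    @property
    def sem_coul(self) -> np.ndarray:
        return self._sem(self.coul_frames)

    @property
    def sem_vdw(self) -> np.ndarray:
        return self._sem(self.vdw_frames)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "partner_chain": [k[0] for k in self.partner_keys],
                "partner_residue": [k[1] for k in self.partner_keys],
                "partner_name": self.partner_names,
                "dE_coul": self.mean_coul,
                "sem_coul": self.sem_coul,
                "dE_vdw": self.mean_vdw,
                "sem_vdw": self.sem_vdw,
                "dE_tot": self.mean_total,
            }
        )


def _pair_energies(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    q_a: np.ndarray,
    q_b: np.ndarray,
    sig_a: np.ndarray,
    sig_b: np.ndarray,
    eps_a: np.ndarray,
    eps_b: np.ndarray,
    box: np.ndarray | None,
    coul_scale: np.ndarray,
    lj_scale: np.ndarray,
    cutoff: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    delta = minimum_image(pos_a[:, None, :] - pos_b[None, :, :], box)
    r = np.linalg.norm(delta, axis=2)
    if np.any(r < 1e-9):
        ia, ib = np.argwhere(r < 1e-9)[0]
        raise ValueError(f"zero interatomic distance between pair ({ia}, {ib})")
    coul = COULOMB_CONSTANT * np.outer(q_a, q_b) / r
    sig = 0.5 * (sig_a[:, None] + sig_b[None, :])
    eps = np.sqrt(np.outer(eps_a, eps_b))
    sr6 = (sig / r) ** 6
    lj = 4.0 * eps * (sr6**2 - sr6)
    if cutoff is not None:
        mask = r <= cutoff
        coul = coul * mask
        lj = lj * mask
    return coul * coul_scale, lj * lj_scale


def residue_interaction_energies(
    traj: Trajectory,
    target_residue: int,
    chain: str | None = None,
    cutoff: float | None = None,
) -> EDAResult:
    """Decompose the target residue's nonbonded energy by partner residue.

    ``target_residue`` is a residue id (resolved with ``chain`` when
    ambiguous).  Every atom needs charge and LJ parameters.  Returns
    per-frame per-partner Coulomb and LJ sums wrapped in
    :class:`EDAResult`.
    """
    system = traj.topology
    missing = [
        a.serial
        for a in system.atoms
        if a.charge is None or a.lj_sigma is None or a.lj_epsilon is None
    ]
    if missing:
        raise ValueError(
            f"atoms without nonbonded parameters: serials {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    target_ri = system.find_residue(target_residue, chain)
    residues = system.residues
    target_atoms = np.array(residues[target_ri].atom_indices)
    partners = [ri for ri in range(len(residues)) if ri != target_ri]

    q = np.array([a.charge for a in system.atoms])
    sig = np.array([a.lj_sigma for a in system.atoms])
    eps = np.array([a.lj_epsilon for a in system.atoms])

    # pair scale factors target x partner, honoring exclusions and 1-4s
    def scales_for(partner_atoms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cs = np.ones((len(target_atoms), len(partner_atoms)))
        ls = np.ones_like(cs)
        for i, a in enumerate(target_atoms):
            for j, b in enumerate(partner_atoms):
                key = tuple(sorted((int(a), int(b))))
                if key in system.exclusions:
                    cs[i, j] = ls[i, j] = 0.0
                elif key in system.scaled14:
                    cs[i, j], ls[i, j] = system.scaled14[key]
        return cs, ls

    partner_scales = {
        ri: scales_for(np.array(residues[ri].atom_indices)) for ri in partners
    }

    n_frames = traj.n_frames
    coul_frames = np.zeros((n_frames, len(partners)))
    vdw_frames = np.zeros((n_frames, len(partners)))
    for f in range(n_frames):
        frame = traj.frames[f]
        box = traj.box[f] if traj.box is not None else None
        for col, ri in enumerate(partners):
            pa = np.array(residues[ri].atom_indices)
            cs, ls = partner_scales[ri]
            coul, lj = _pair_energies(
                frame[target_atoms], frame[pa],
                q[target_atoms], q[pa],
                sig[target_atoms], sig[pa],
                eps[target_atoms], eps[pa],
                box, cs, ls, cutoff,
            )
            coul_frames[f, col] = coul.sum()
            vdw_frames[f, col] = lj.sum()

    target = residues[target_ri]
    return EDAResult(
        target_key=(target.chain, target.residue_id),
        partner_keys=[(residues[ri].chain, residues[ri].residue_id) for ri in partners],
        partner_names=[residues[ri].name for ri in partners],
        coul_frames=coul_frames,
        vdw_frames=vdw_frames,
    )


@dataclass
class EDATotal:
    """Summed interaction of the target with all partners, with frame SEM."""

    coul: float
    vdw: float
    total: float
    sem_coul: float
    sem_vdw: float
    sem_total: float


def eda_total(result: EDAResult) -> EDATotal:
    """Totals over all partners; SEM computed from per-frame totals."""
    if len(result.partner_keys) == 0:
        raise ValueError("EDA result has no partners")
    coul_t = result.coul_frames.sum(axis=1)
    vdw_t = result.vdw_frames.sum(axis=1)
    tot_t = coul_t + vdw_t

    def sem(x: np.ndarray) -> float:
        if x.size < 2:
            return 0.0
        return float(x.std(ddof=1) / np.sqrt(x.size))

    return EDATotal(
        coul=float(coul_t.mean()),
        vdw=float(vdw_t.mean()),
        total=float(tot_t.mean()),
        sem_coul=sem(coul_t),
        sem_vdw=sem(vdw_t),
        sem_total=sem(tot_t),
    )


@dataclass
class EDADifference:
    """Per-partner differences b - a with quadrature uncertainties."""

    partner_keys: list[tuple[str, int]]
    d_coul: np.ndarray
    d_vdw: np.ndarray
    d_total: np.ndarray
    sigma_coul: np.ndarray
    sigma_vdw: np.ndarray
    one_sided: list[tuple[str, int]] = field(default_factory=list)


def eda_difference(a: EDAResult, b: EDAResult) -> EDADifference:
    """Partner-matched differences ``b - a`` (mutant minus wild type).

    Partners are matched by (chain, residue_id); partners present in only
    one result are flagged one-sided and contribute their own value (with
    sign) as the difference.
    """
    a_map = {k: i for i, k in enumerate(a.partner_keys)}
    b_map = {k: i for i, k in enumerate(b.partner_keys)}
    keys = sorted(set(a_map) | set(b_map))
    d_coul, d_vdw, s_coul, s_vdw = [], [], [], []
    one_sided = []
    for k in keys:
        ia, ib = a_map.get(k), b_map.get(k)
        ac = a.mean_coul[ia] if ia is not None else 0.0
        av = a.mean_vdw[ia] if ia is not None else 0.0
        asc = a.sem_coul[ia] if ia is not None else 0.0
        asv = a.sem_vdw[ia] if ia is not None else 0.0
        bc = b.mean_coul[ib] if ib is not None else 0.0
        bv = b.mean_vdw[ib] if ib is not None else 0.0
        bsc = b.sem_coul[ib] if ib is not None else 0.0
        bsv = b.sem_vdw[ib] if ib is not None else 0.0
        if ia is None or ib is None:
            one_sided.append(k)
        d_coul.append(bc - ac)
        d_vdw.append(bv - av)
        s_coul.append(np.hypot(asc, bsc))
        s_vdw.append(np.hypot(asv, bsv))
    d_coul = np.array(d_coul)
    d_vdw = np.array(d_vdw)
    return EDADifference(
        partner_keys=keys,
        d_coul=d_coul,
        d_vdw=d_vdw,
        d_total=d_coul + d_vdw,
        sigma_coul=np.array(s_coul),
        sigma_vdw=np.array(s_vdw),
        one_sided=one_sided,
    )
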