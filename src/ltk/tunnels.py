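"""Grid-based detection and ranking of intramolecular tunnels.

The protein is treated as hard spheres with van der Waals radii.  A
regular grid stores the free radius of every voxel (distance from the
voxel center to the nearest atom *surface*).  Tunnels from an active-site
seed to the protein surface are lowest-cost paths under the CAVER-style
edge cost

    cost(edge) = step_length / r_mid**nu

with r_mid the mean free radius of the two voxels and nu = 2 by default,
found by Dijkstra search with 26-connectivity.  A tunnel's throughput is
exp(-cost), its curvature the arc length over the straight seed-to-exit
distance, and its bottleneck the minimum free radius along the path.
Tunnels found across trajectory snapshots are clustered by average
node-to-node distance to report per-cluster occurrence fractions (the
fraction of snapshots in which a geometrically equivalent tunnel exists).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _sparse_dijkstra
from scipy.spatial import cKDTree

from .core import MolecularSystem, ScalarGrid

__all__ = [
    "Tunnel",
    "TunnelMetrics",
    "TunnelEnsemble",
    "SeedBuriedError",
    "free_radius_grid",
    "find_tunnels",
    "tunnel_metrics",
    "cluster_tunnels",
    "export_tunnels_pdb",
    "metrics_table",
]


class SeedBuriedError(ValueError):
    """The search seed sits in a voxel narrower than the probe."""


@dataclass
class Tunnel:
    """An ordered voxel-center polyline from seed to surface."""

    nodes: np.ndarray  # (n, 3) angstrom
    radii: np.ndarray  # (n,) free radius per node
    cost: float

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        if len(self.nodes) != len(self.radii):
            raise ValueError("nodes and radii must be congruent")
        if self.cost < 0:
            raise ValueError("cost must be >= 0")

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class TunnelMetrics:
    """Length, curvature, bottleneck and throughput of one tunnel."""

    length: float
    curvature: float
    bottleneck: float
    throughput: float


@dataclass
class TunnelEnsemble:
    """Tunnel clusters across snapshots with occurrence fractions."""

    clusters: list[list[tuple[int, Tunnel]]]  # (snapshot index, tunnel)
    occurrence: np.ndarray
    n_snapshots: int


def free_radius_grid(
    system: MolecularSystem,
    spacing: float = 0.6,
    padding: float = 4.0,
    k_neighbors: int = 16,
    align_to: np.ndarray | None = None,
) -> ScalarGrid:
    """Free radius (distance to the nearest atom surface) on a regular grid.

    Voxel value = max(0, min_i(|v - c_i| - R_i)).  The grid spans the atom
    bounding box plus ``padding`` on all sides so that boundary voxels lie
    in solvent.  ``align_to`` shifts the origin (by under one spacing) so
    that the given point falls exactly on a voxel center — useful to probe
    the free radius at a search seed without half-voxel offset.  Nearest-
    surface distances use a k-nearest-neighbor query with an exact
    fallback for the rare voxels where differing radii could change the
    minimizer beyond the k-th neighbor.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    coords = system.coordinates
    radii = np.array([a.vdw_radius for a in system.atoms], dtype=float)
    if any(a.vdw_radius is None for a in system.atoms):
        raise ValueError("all atoms need vdw_radius; call assign_vdw_radii first")
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    if align_to is not None:
        align_to = np.asarray(align_to, dtype=float)
        shift = (align_to - lo) % spacing
        lo = lo - (spacing - shift) % spacing
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
    grid = ScalarGrid(origin=lo, spacing=spacing, values=np.zeros(shape))
    points = grid.voxel_centers().reshape(-1, 3)

    tree = cKDTree(coords)
    k = min(k_neighbors, len(coords))
    dists, idx = tree.query(points, k=k, workers=-1)
    if k == 1:
        dists, idx = dists[:, None], idx[:, None]
    free = np.min(dists - radii[idx], axis=1)
    # an unseen atom could still win only if d - r_max < current best
    r_max, r_min = radii.max(), radii.min()
    suspect = np.where(dists[:, -1] - r_max < free)[0]
    for p in suspect:
        near = tree.query_ball_point(points[p], free[p] + r_max + 1e-9)
        if near:
            free[p] = min(free[p], np.min(np.linalg.norm(coords[near] - points[p], axis=1) - radii[near]))
    grid.values = np.clip(free, 0.0, None).reshape(shape)
    return grid


_NEIGHBOR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


def _build_graph(
    free: np.ndarray,
    passable: np.ndarray,
    spacing: float,
    nu: float,
) -> coo_matrix:
    """Sparse 26-connectivity cost graph over passable voxels."""
    shape = free.shape
    n = free.size
    flat = np.arange(n).reshape(shape)
    rows, cols, costs = [], [], []
    for off in _NEIGHBOR_OFFSETS:
        # take only the 13 positive-lexicographic offsets; matrix is symmetrized
        if tuple(off) >= (0, 0, 0) and not (tuple(off) > (0, 0, 0)):
            continue
        if tuple(off) < (0, 0, 0):
            continue
        src = [
            slice(None, -o) if o > 0 else slice(-o, None) if o < 0 else slice(None)
            for o in off
        ]
        dst = [
            slice(o, None) if o > 0 else slice(None, o) if o < 0 else slice(None)
            for o in off
        ]
        ok = passable[tuple(src)] & passable[tuple(dst)]
        a = flat[tuple(src)][ok]
        b = flat[tuple(dst)][ok]
        r_mid = 0.5 * (free.reshape(-1)[a] + free.reshape(-1)[b])
        step = spacing * float(np.linalg.norm(off))
        w = step / np.maximum(r_mid, 1e-12) ** nu
        rows.append(a)
        cols.append(b)
        costs.append(w)
    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    costs = np.concatenate(costs) if costs else np.array([])
    return coo_matrix(
        (np.concatenate([costs, costs]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()


def _surface_mask(shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[0, :, :] = mask[-1, :, :] = True
    mask[:, 0, :] = mask[:, -1, :] = True
    mask[:, :, 0] = mask[:, :, -1] = True
    return mask


def find_tunnels(
    grid: ScalarGrid,
    seed: np.ndarray,
    probe_radius: float = 1.2,
    max_tunnels: int = 3,
    nu: float = 2.0,
) -> list[Tunnel]:
    """Lowest-cost seed-to-surface paths on the free-radius grid.

    Voxels with free radius below ``probe_radius`` are impassable.  After
    each returned tunnel, voxels within (bottleneck + probe_radius) of its
    nodes are blocked so subsequent searches yield geometrically distinct
    tunnels.  Ties between equal-cost surface exits break on the smaller
    flat voxel index for determinism.  Returns tunnels in ascending cost;
    an empty list when no surface is reachable.
    """
    free = grid.values
    shape = free.shape
    seed_idx = grid.index_of(seed)
    if free[seed_idx] < probe_radius:
        raise SeedBuriedError(
            f"seed {np.asarray(seed)} is buried: free radius "
            f"{free[seed_idx]:.2f} < probe {probe_radius:.2f}"
        )
    passable = free >= probe_radius
    surface = _surface_mask(shape)
    seed_flat = int(np.ravel_multi_index(seed_idx, shape))

    tunnels: list[Tunnel] = []
    blocked = np.zeros(shape, dtype=bool)
    centers_flat = grid.voxel_centers().reshape(-1, 3)
    for _ in range(max_tunnels):
        current = passable & ~blocked
        if not current[seed_idx]:
            break
        graph = _build_graph(free, current, grid.spacing, nu)
        dist, pred = _sparse_dijkstra(
            graph, indices=seed_flat, return_predecessors=True
        )
        exit_candidates = np.where(surface.reshape(-1) & current.reshape(-1))[0]
        finite = exit_candidates[np.isfinite(dist[exit_candidates])]
        if finite.size == 0:
            break
        best_cost = dist[finite].min()
        # deterministic tie-break: smallest flat index among equal costs
        winners = finite[np.isclose(dist[finite], best_cost, rtol=0, atol=1e-12)]
        target = int(winners.min())
        path = [target]
        while path[-1] != seed_flat:
            path.append(int(pred[path[-1]]))
        path.reverse()
        nodes = centers_flat[path]
        radii = free.reshape(-1)[path]
        tunnels.append(Tunnel(nodes=nodes, radii=radii, cost=float(dist[target])))
        # suppress near-duplicate paths in later iterations
        bottleneck = radii.min()
        block_r = bottleneck + probe_radius
        tree = cKDTree(nodes)
        open_voxels = np.where(current.reshape(-1))[0]
        near = tree.query_ball_point(centers_flat[open_voxels], block_r)
        hit = open_voxels[[len(h) > 0 for h in near]]
        # keep the seed's vicinity open so distinct tunnels sharing the
        # active-site entrance (e.g. opposite exits) remain findable
        seed_center = grid.center_of(seed_idx)
        hit = hit[np.linalg.norm(centers_flat[hit] - seed_center, axis=1) > block_r]
        blocked.reshape(-1)[hit] = True
        blocked[seed_idx] = False
    tunnels.sort(key=lambda t: t.cost)
    return tunnels


def tunnel_metrics(tunnel: Tunnel) -> TunnelMetrics:
    """Arc length, curvature, bottleneck and exp(-cost) throughput."""
    if len(tunnel) < 2:
        raise ValueError("tunnel metrics need at least 2 nodes")
    segs = np.diff(tunnel.nodes, axis=0)
    length = float(np.linalg.norm(segs, axis=1).sum())
    straight = float(np.linalg.norm(tunnel.nodes[-1] - tunnel.nodes[0]))
    curvature = length / straight if straight > 1e-12 else np.inf
    return TunnelMetrics(
        length=length,
        curvature=curvature,
        bottleneck=float(tunnel.radii.min()),
        throughput=float(np.exp(-tunnel.cost)),
    )


def _resample_polyline(nodes: np.ndarray, n_points: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] < 1e-12:
        return np.tile(nodes[0], (n_points, 1))
    t = np.linspace(0.0, s[-1], n_points)
    return np.stack([np.interp(t, s, nodes[:, d]) for d in range(3)], axis=1)


def cluster_tunnels(
    tunnels_by_snapshot: Sequence[Sequence[Tunnel]],
    match_threshold: float = 2.0,
    n_resample: int = 20,
) -> TunnelEnsemble:
    """Single-linkage clustering of tunnels across snapshots.

    Tunnels are arc-length resampled to ``n_resample`` nodes; the distance
    between two tunnels is the mean node-to-node distance.  Clusters merge
    below ``match_threshold``.  Occurrence of a cluster is the fraction of
    snapshots contributing at least one member.
    """
    if len(tunnels_by_snapshot) == 0:
        raise ValueError("need at least one snapshot")
    n_snap = len(tunnels_by_snapshot)
    flat: list[tuple[int, Tunnel]] = [
        (si, t) for si, snap in enumerate(tunnels_by_snapshot) for t in snap
    ]
    if not flat:
        return TunnelEnsemble(clusters=[], occurrence=np.array([]), n_snapshots=n_snap)
    profiles = np.array([_resample_polyline(t.nodes, n_resample) for _, t in flat])
    n = len(flat)
    if n == 1:
        labels = np.array([1])
    else:
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import pdist

        # condensed mean node-to-node distance matrix
        diffs = profiles[:, None, :, :] - profiles[None, :, :, :]
        dmat = np.linalg.norm(diffs, axis=3).mean(axis=2)
        condensed = dmat[np.triu_indices(n, k=1)]
        labels = fcluster(linkage(condensed, method="single"), t=match_threshold, criterion="distance")
    clusters: dict[int, list[tuple[int, Tunnel]]] = {}
    for lab, item in zip(labels, flat):
        clusters.setdefault(lab, []).append(item)
    ordered = sorted(clusters.values(), key=lambda c: min(t.cost for _, t in c))
    occurrence = np.array(
        [len({si for si, _ in c}) / n_snap for c in ordered]
    )
    return TunnelEnsemble(clusters=ordered, occurrence=occurrence, n_snapshots=n_snap)


def export_tunnels_pdb(tunnels: Sequence[Tunnel], path: str | Path) -> None:
    """Write tunnels as pseudo-atom chains (B-factor = node free radius)."""
    with open(path, "w") as fh:
        serial = 1
        for ti, tunnel in enumerate(tunnels):
            chain = chr(ord("A") + ti % 26)
            for ni, (node, radius) in enumerate(zip(tunnel.nodes, tunnel.radii)):
                fh.write(
                    f"HETATM{serial % 100000:>5d}  C   TUN {chain}{(ni + 1) % 10000:>4d}    "
                    f"{node[0]:8.3f}{node[1]:8.3f}{node[2]:8.3f}{1.0:6.2f}{radius:6.2f}"
                    f"           C\n"
                )
                serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def metrics_table(tunnels: Sequence[Tunnel]):
    """Per-tunnel metrics as a pandas DataFrame (for CSV reports)."""
    import pandas as pd

    rows = []
    for i, t in enumerate(tunnels):
        m = tunnel_metrics(t)
        rows.append(
            {
                "tunnel": i,
                "cost": t.cost,
                "length_A": m.length,
                "curvature": m.curvature,
                "bottleneck_A": m.bottleneck,
                "throughput": m.throughput,
            }
        )
    return pd.DataFrame(rows)
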