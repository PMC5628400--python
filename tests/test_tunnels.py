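import itertools

import numpy as np
import pytest

from ltk.core import ScalarGrid
from ltk.synthetic import ChannelSpec, make_channel_system
from ltk.tunnels import (
    SeedBuriedError,
    Tunnel,
    cluster_tunnels,
    export_tunnels_pdb,
    find_tunnels,
    free_radius_grid,
    metrics_table,
    tunnel_metrics,
)
from ltk.synthetic import make_point_charge_system


def single_atom_system(radius=1.5):
    system = make_point_charge_system([[0.0, 0.0, 0.0]], [0.0])
    system.atoms[0].vdw_radius = radius
    return system


class TestFreeRadiusGrid:
    def test_single_atom_distance_minus_radius(self):
        grid = free_radius_grid(single_atom_system(1.5), spacing=1.0, padding=4.0,
                                align_to=np.zeros(3))
        assert grid.values[grid.index_of([3.0, 0.0, 0.0])] == pytest.approx(1.5)

    def test_clamped_inside_atom(self):
        grid = free_radius_grid(single_atom_system(1.5), spacing=0.5, padding=3.0,
                                align_to=np.zeros(3))
        assert grid.values[grid.index_of([0.0, 0.0, 0.0])] == 0.0

    def test_channel_axis_voxels_near_inner_radius(self, open_channel):
        spec, _, grid, _ = open_channel
        for z in (-5.0, 0.0, 5.0):
            val = grid.values[grid.index_of([0.0, 0.0, z])]
            assert val == pytest.approx(spec.inner_radius, abs=0.3)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            free_radius_grid(single_atom_system(), spacing=0.0)


class TestFindTunnels:
    def test_open_channel_single_tunnel_through_cap(self, open_channel):
        spec, _, grid, tunnels = open_channel
        assert len(tunnels) == 1
        t = tunnels[0]
        # exits through the open (negative-axis) cap
        assert t.nodes[-1][2] < -spec.length / 2
        m = tunnel_metrics(t)
        assert m.bottleneck == pytest.approx(spec.inner_radius, abs=grid.spacing / 2)
        assert m.curvature == pytest.approx(1.0, abs=0.05)

    def test_closed_channel_finds_nothing(self, closed_channel):
        _, _, grid = closed_channel
        assert find_tunnels(grid, np.zeros(3), probe_radius=1.2) == []

    def test_two_open_caps_two_tunnels_equal_cost(self):
        spec = ChannelSpec(cap_open=(True, True))
        system = make_channel_system(spec, seed=1)
        grid = free_radius_grid(system, spacing=0.6, align_to=np.zeros(3))
        tunnels = find_tunnels(grid, np.zeros(3), probe_radius=1.2, max_tunnels=4)
        assert len(tunnels) == 2
        assert tunnels[0].cost == pytest.approx(tunnels[1].cost, rel=0.05)
        exit_z = sorted(t.nodes[-1][2] for t in tunnels)
        assert exit_z[0] < -spec.length / 2 < spec.length / 2 < exit_z[1]

    def test_buried_seed_raises(self, open_channel):
        _, _, grid, _ = open_channel
        with pytest.raises(SeedBuriedError, match="buried"):
            # a point inside the wall tube
            find_tunnels(grid, np.array([4.5, 0.0, 0.0]), probe_radius=1.2)

    def test_probe_radius_monotonicity(self, open_channel):
        _, _, grid, _ = open_channel
        costs, reachable = [], []
        for probe in (0.8, 1.2, 1.6):
            ts = find_tunnels(grid, np.zeros(3), probe_radius=probe, max_tunnels=1)
            costs.append(ts[0].cost if ts else np.inf)
            reachable.append(int(np.sum((grid.values >= probe))))
        assert costs == sorted(costs)
        assert reachable == sorted(reachable, reverse=True)

    def test_refinement_convergence_of_bottleneck(self):
        spec = ChannelSpec(inner_radius=3.0, length=14.0, cap_open=(True, False))
        system = make_channel_system(spec, seed=2)
        bottlenecks = []
        for spacing in (1.0, 0.5):
            grid = free_radius_grid(system, spacing=spacing, align_to=np.zeros(3))
            ts = find_tunnels(grid, np.zeros(3), probe_radius=1.2, max_tunnels=1)
            bottlenecks.append(tunnel_metrics(ts[0]).bottleneck)
        assert abs(bottlenecks[1] - bottlenecks[0]) < 0.5

    def test_bottleneck_is_minimum_radius(self, open_channel):
        _, _, _, tunnels = open_channel
        t = tunnels[0]
        assert tunnel_metrics(t).bottleneck == pytest.approx(t.radii.min())
        assert np.all(t.radii >= tunnel_metrics(t).bottleneck)


class TestDijkstraOptimality:
    """Cross-check grid Dijkstra against independent shortest-path oracles."""

    @staticmethod
    def edge_cost(free, a, b, spacing, nu=2.0):
        step = spacing * np.linalg.norm(np.array(a) - np.array(b))
        r_mid = 0.5 * (free[a] + free[b])
        return step / r_mid**nu

    def brute_force_min_cost(self, free, spacing, start, targets):
        """Exhaustive DFS over simple paths with branch-and-bound."""
        shape = free.shape
        cells = list(itertools.product(*[range(s) for s in shape]))
        best = [np.inf]

        def neighbors(c):
            for off in itertools.product((-1, 0, 1), repeat=3):
                if off == (0, 0, 0):
                    continue
                n = tuple(np.array(c) + off)
                if all(0 <= n[d] < shape[d] for d in range(3)):
                    yield n

        def dfs(node, cost, visited):
            if cost >= best[0]:
                return
            if node in targets:
                best[0] = cost
                return
            for n in neighbors(node):
                if n not in visited:
                    dfs(n, cost + self.edge_cost(free, node, n, spacing), visited | {n})

        dfs(start, 0.0, {start})
        return best[0]

    def test_matches_exhaustive_enumeration_small_grid(self):
        rng = np.random.default_rng(8)
        free = rng.uniform(1.5, 4.0, size=(3, 3, 3))
        grid = ScalarGrid(origin=np.zeros(3), spacing=1.0, values=free)
        tunnels = find_tunnels(grid, np.array([1.0, 1.0, 1.0]), probe_radius=1.0, max_tunnels=1)
        surface = {
            c
            for c in itertools.product(range(3), repeat=3)
            if 0 in c or 2 in c
        }
        brute = self.brute_force_min_cost(free, 1.0, (1, 1, 1), surface)
        assert tunnels[0].cost == pytest.approx(brute, rel=1e-10)

    def test_matches_networkx_on_5cube(self):
        import networkx as nx

        rng = np.random.default_rng(9)
        free = rng.uniform(1.5, 4.0, size=(5, 5, 5))
        grid = ScalarGrid(origin=np.zeros(3), spacing=1.0, values=free)
        tunnels = find_tunnels(grid, np.array([2.0, 2.0, 2.0]), probe_radius=1.0, max_tunnels=1)

        g = nx.Graph()
        for c in itertools.product(range(5), repeat=3):
            for off in itertools.product((-1, 0, 1), repeat=3):
                if off == (0, 0, 0):
                    continue
                n = tuple(np.array(c) + off)
                if all(0 <= n[d] < 5 for d in range(3)):
                    g.add_edge(c, n, weight=self.edge_cost(free, c, n, 1.0))
        surface = [c for c in g.nodes if 0 in c or 4 in c]
        lengths = nx.single_source_dijkstra_path_length(g, (2, 2, 2))
        best = min(lengths[s] for s in surface)
        assert tunnels[0].cost == pytest.approx(best, rel=1e-10)


class TestTunnelMetrics:
    def test_straight_path_curvature_one(self):
        t = Tunnel(nodes=[[0, 0, 0], [0, 0, 1], [0, 0, 2]], radii=[2, 2, 2], cost=0.5)
        m = tunnel_metrics(t)
        assert m.curvature == pytest.approx(1.0)
        assert m.length == pytest.approx(2.0)

    def test_zero_cost_full_throughput(self):
        t = Tunnel(nodes=[[0, 0, 0], [1, 0, 0]], radii=[2, 2], cost=0.0)
        assert tunnel_metrics(t).throughput == 1.0

    def test_l_shape_curvature(self):
        # two 5 A legs: length 10, straight 5 sqrt(2), curvature sqrt(2)
        t = Tunnel(
            nodes=[[0, 0, 0], [5, 0, 0], [5, 5, 0]], radii=[2, 2, 2], cost=1.0
        )
        m = tunnel_metrics(t)
        assert m.length == pytest.approx(10.0)
        assert m.curvature == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_single_node_rejected(self):
        t = Tunnel(nodes=[[0, 0, 0]], radii=[2], cost=0.0)
        with pytest.raises(ValueError, match="2 nodes"):
            tunnel_metrics(t)


class TestClusterTunnels:
    @staticmethod
    def straight_tunnel(offset=0.0, n=10, jitter=None, seed=0):
        nodes = np.stack(
            [np.full(n, offset), np.zeros(n), np.linspace(0, 10, n)], axis=1
        )
        if jitter is not None:
            nodes = nodes + np.random.default_rng(seed).uniform(-jitter, jitter, nodes.shape)
        return Tunnel(nodes=nodes, radii=np.full(n, 2.0), cost=1.0)

    def test_occurrence_counts_snapshots(self):
        snaps = [[self.straight_tunnel()] if i < 3 else [] for i in range(10)]
        ens = cluster_tunnels(snaps, match_threshold=2.0)
        assert len(ens.clusters) == 1
        assert ens.occurrence[0] == pytest.approx(0.30)

    def test_two_separate_channels_two_clusters(self):
        snaps = [
            [self.straight_tunnel(0.0), self.straight_tunnel(20.0)] for _ in range(5)
        ]
        ens = cluster_tunnels(snaps, match_threshold=2.0)
        assert len(ens.clusters) == 2
        np.testing.assert_allclose(ens.occurrence, [1.0, 1.0])

    def test_jittered_copies_merge_below_threshold(self):
        snaps = [
            [self.straight_tunnel(jitter=0.5, seed=i)] for i in range(6)
        ]
        ens = cluster_tunnels(snaps, match_threshold=2.0)
        assert len(ens.clusters) == 1
        assert ens.occurrence[0] == 1.0

    def test_empty_snapshots_empty_ensemble(self):
        ens = cluster_tunnels([[], []], match_threshold=2.0)
        assert ens.clusters == []


class TestExports:
    def test_pdb_export_has_one_hetatm_per_node(self, tmp_path):
        t = Tunnel(nodes=[[0, 0, 0], [1, 0, 0], [2, 0, 0]], radii=[2, 2.5, 3], cost=1.0)
        path = tmp_path / "tunnels.pdb"
        export_tunnels_pdb([t], path)
        lines = [l for l in path.read_text().splitlines() if l.startswith("HETATM")]
        assert len(lines) == 3
        # B-factor column carries the node free radius
        assert float(lines[1][60:66]) == pytest.approx(2.5)

    def test_metrics_table_columns(self):
        t = Tunnel(nodes=[[0, 0, 0], [1, 0, 0]], radii=[2, 2], cost=1.0)
        df = metrics_table([t])
        assert list(df.columns) == [
            "tunnel", "cost", "length_A", "curvature", "bottleneck_A", "throughput",
        ]
        assert df.loc[0, "throughput"] == pytest.approx(np.exp(-1.0))
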