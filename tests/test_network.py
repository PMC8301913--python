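"""Dynamical network construction and optimal/suboptimal path search."""

import math
import warnings

import networkx as nx
import numpy as np
import pytest

import netdyn as nd
from netdyn.errors import NoPathError, ParameterError
from netdyn.network import (
    ContactOccupancy,
    CorrelationMatrix,
    DynamicalNetwork,
    NetworkParams,
    PathQuery,
    build_network,
    build_network_from_trajectory,
    contact_occupancy,
    cross_correlation,
    interface_edge_summary,
    optimal_path,
    suboptimal_paths,
    to_edge_table,
    windowed_networks,
)

CA_PARAMS = NetworkParams(contact_mode="ca")


def make_net(n_nodes, weighted_edges):
    """Hand-built network: nodes 0..n-1 on one chain, explicit weights."""
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for i, j, w in weighted_edges:
        g.add_edge(i, j, weight=w, occupancy=1.0,
                   correlation=math.exp(-w))
    residues = tuple(("A", i + 1, "") for i in range(n_nodes))
    return DynamicalNetwork(g, residues, NetworkParams())


def enumerate_simple_paths(g, s, t):
    """Independent oracle: exhaustive DFS over all simple s-t paths."""
    out = []

    def walk(node, visited, weight):
        if node == t:
            out.append((weight, tuple(visited)))
            return
        for nxt in g[node]:
            if nxt not in visited:
                walk(nxt, visited + [nxt],
                     weight + g[node][nxt]["weight"])

    walk(s, [s], 0.0)
    return sorted(out)


class TestContactOccupancy:
    def _toggling_trajectory(self, n_frames, n_in):
        """Chain-B residue 1 contacts chain-A residue 1 (4.0 Å) in exactly
        the first ``n_in`` frames; chain B is otherwise 100 Å away."""
        st = nd.make_toy_fold(8, "two_chain")  # chains of 4 residues
        frames = np.repeat(st.coords[None], n_frames, axis=0)
        frames[:, 4:, 1] = 100.0
        frames[:n_in, 4, 1] = 4.0
        return nd.Trajectory(st, frames)

    def test_boundary_75_percent_inclusive(self):
        traj = self._toggling_trajectory(8, 6)
        occ = contact_occupancy(traj, CA_PARAMS)
        assert occ.fractions[0, 4] == pytest.approx(0.75)
        corr = CorrelationMatrix(np.full((8, 8), 0.5) + 0.5 * np.eye(8),
                                 occ.residues)
        net = build_network(occ, corr, CA_PARAMS)
        assert net.graph.has_edge(0, 4)

    def test_below_threshold_excluded(self):
        traj = self._toggling_trajectory(100, 74)
        occ = contact_occupancy(traj, CA_PARAMS)
        assert occ.fractions[0, 4] == pytest.approx(0.74)
        corr = CorrelationMatrix(np.full((8, 8), 0.5) + 0.5 * np.eye(8),
                                 occ.residues)
        net = build_network(occ, corr, CA_PARAMS)
        assert not net.graph.has_edge(0, 4)

    def test_never_in_contact(self):
        traj = self._toggling_trajectory(10, 0)
        occ = contact_occupancy(traj, CA_PARAMS)
        assert occ.fractions[0, 4] == 0.0

    def test_planted_occupancy_interval(self):
        ref = nd.make_toy_fold(10, "helix")
        model = nd.plant_contact(nd.isotropic_model(ref, 0.3), 0, 3,
                                 occupancy=0.9)
        traj = nd.sample_trajectory(model, nd.GeneratorConfig(2000, seed=13))
        occ = contact_occupancy(traj, CA_PARAMS)
        assert 0.87 <= occ.fractions[0, 3] <= 0.93

    def test_matrix_invariants(self, benchmark_trajectory):
        _, _, traj = benchmark_trajectory
        occ = contact_occupancy(traj, CA_PARAMS)
        np.testing.assert_array_equal(occ.fractions, occ.fractions.T)
        np.testing.assert_array_equal(np.diag(occ.fractions), 1.0)
        assert occ.fractions.min() >= 0 and occ.fractions.max() <= 1


class TestCrossCorrelation:
    def test_diagonal_and_range(self, benchmark_trajectory):
        _, _, traj = benchmark_trajectory
        C = cross_correlation(traj)
        np.testing.assert_allclose(np.diag(C.values), 1.0)
        assert np.abs(C.values).max() <= 1.0
        np.testing.assert_allclose(C.values, C.values.T, atol=1e-12)

    def test_identical_displacements_give_unity(self):
        # large system: the mean-structure superposition is then a
        # near-identity and cannot decorrelate the mirrored pair
        ref = nd.make_toy_fold(100, "helix")
        rng = np.random.default_rng(0)
        base = rng.standard_normal((300, 100, 3)) * 0.3
        base[:, 1] = base[:, 0]  # residue 1 mirrors residue 0
        traj = nd.Trajectory(ref, ref.coords[None] + base)
        C = cross_correlation(traj)
        assert C.values[0, 1] >= 0.99

    def test_planted_value_recovered(self, helix100):
        model = nd.plant_correlated_path(
            nd.isotropic_model(helix100, 0.5), [0, 1, 2], 0.9)
        traj = nd.sample_trajectory(model, nd.GeneratorConfig(10_000, seed=17))
        C = cross_correlation(traj)
        assert C.values[0, 1] == pytest.approx(0.9, abs=0.05)
        assert C.values[1, 2] == pytest.approx(0.9, abs=0.05)


class TestBuildNetwork:
    def _occ_corr(self, f01, c01):
        residues = (("A", 1, ""), ("A", 3, ""), ("B", 1, ""))
        f = np.eye(3)
        f[0, 1] = f[1, 0] = f01
        f[0, 2] = f[2, 0] = 1.0
        c = np.eye(3)
        c[0, 1] = c[1, 0] = c01
        c[0, 2] = c[2, 0] = 0.5
        return ContactOccupancy(f, residues), CorrelationMatrix(c, residues)

    def test_weight_is_minus_log_correlation(self):
        occ, corr = self._occ_corr(1.0, 1.0)
        net = build_network(occ, corr)
        assert net.graph[0][1]["weight"] == pytest.approx(0.0)
        assert net.graph[0][2]["weight"] == pytest.approx(math.log(2))

    def test_half_correlation(self):
        occ, corr = self._occ_corr(1.0, 0.5)
        net = build_network(occ, corr)
        assert net.graph[0][1]["weight"] == pytest.approx(0.693, abs=1e-3)

    def test_subthreshold_occupancy_excluded(self):
        occ, corr = self._occ_corr(0.74, 0.9)
        net = build_network(occ, corr)
        assert not net.graph.has_edge(0, 1)

    def test_zero_correlation_edge_dropped_with_warning(self):
        occ, corr = self._occ_corr(1.0, 0.0)
        with pytest.warns(UserWarning, match="zero correlation"):
            net = build_network(occ, corr)
        assert not net.graph.has_edge(0, 1)

    def test_sequence_neighbours_excluded(self):
        residues = (("A", 1, ""), ("A", 2, ""))
        occ = ContactOccupancy(np.ones((2, 2)), residues)
        corr = CorrelationMatrix(np.full((2, 2), 0.9) + 0.1 * np.eye(2),
                                 residues)
        net = build_network(occ, corr)
        assert net.graph.number_of_edges() == 0
        relaxed = build_network(occ, corr, NetworkParams(exclude_neighbors=0))
        assert relaxed.graph.number_of_edges() == 1

    def test_raising_threshold_never_adds_edges(self, benchmark_trajectory):
        _, _, traj = benchmark_trajectory
        lo = build_network_from_trajectory(
            traj, NetworkParams(contact_mode="ca", occupancy_threshold=0.5))
        hi = build_network_from_trajectory(
            traj, NetworkParams(contact_mode="ca", occupancy_threshold=0.9))
        assert set(hi.graph.edges()) <= set(lo.graph.edges())


class TestPaths:
    def test_single_edge(self):
        net = make_net(2, [(0, 1, 0.3)])
        p = optimal_path(net, PathQuery(0, 1))
        assert p.nodes == (0, 1)
        assert p.weight == pytest.approx(0.3)

    def test_grid_symmetry_and_tie_break(self):
        w = 0.5
        edges = []
        for r in range(3):
            for c in range(3):
                n = 3 * r + c
                if c < 2:
                    edges.append((n, n + 1, w))
                if r < 2:
                    edges.append((n, n + 3, w))
        net = make_net(9, edges)
        p = optimal_path(net, PathQuery(0, 8))
        assert p.weight == pytest.approx(4 * w)
        # lexicographically smallest of the equal-weight corner paths
        assert p.nodes == (0, 1, 2, 5, 8)

    def test_disconnected_reports_components(self):
        net = make_net(5, [(0, 1, 1.0), (2, 3, 1.0), (3, 4, 1.0)])
        with pytest.raises(NoPathError, match="component sizes"):
            optimal_path(net, PathQuery(0, 4))

    def test_zero_tolerance_unique_optimum(self):
        net = make_net(4, [(0, 1, 0.1), (1, 3, 0.1), (0, 2, 0.5), (2, 3, 0.5)])
        ens = suboptimal_paths(net, PathQuery(0, 3, tolerance=0.0))
        assert len(ens.paths) == 1
        assert ens.paths[0].nodes == (0, 1, 3)

    def test_hop_count_mode_prefers_fewest_edges(self):
        # cheap-but-long route vs expensive 2-edge route
        net = make_net(5, [(0, 1, 0.01), (1, 2, 0.01), (2, 3, 0.01),
                           (3, 4, 0.01), (0, 2, 1.0), (2, 4, 1.0)])
        weighted = optimal_path(net, PathQuery(0, 4))
        assert weighted.nodes == (0, 1, 2, 3, 4)
        hops = optimal_path(net, PathQuery(0, 4, hop_count=True))
        assert hops.nodes == (0, 2, 4)
        assert hops.weight == 2.0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ParameterError):
            PathQuery(0, 3, tolerance=-1.0)

    def test_endpoint_frequency_equals_path_count(self):
        net = make_net(5, [(0, 1, 0.2), (1, 4, 0.2), (0, 2, 0.3),
                           (2, 4, 0.3), (0, 3, 0.4), (3, 4, 0.4)])
        ens = suboptimal_paths(net, PathQuery(0, 4, tolerance=1.0))
        assert ens.node_frequency[0] == len(ens.paths)
        assert ens.node_frequency[4] == len(ens.paths)

    def test_removing_unused_edge_is_neutral(self):
        edges = [(0, 1, 0.2), (1, 4, 0.2), (0, 2, 0.3), (2, 4, 0.3),
                 (0, 3, 5.0), (3, 4, 5.0)]
        net = make_net(5, edges)
        q = PathQuery(0, 4, tolerance=0.5)
        before = suboptimal_paths(net, q)
        assert all((0, 3) != p.nodes[:2] for p in before.paths)
        net.graph.remove_edge(0, 3)
        after = suboptimal_paths(net, q)
        assert before.paths == after.paths

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_enumeration(self, seed):
        """Optimal and suboptimal results equal brute-force DFS on random
        graphs of up to 8 nodes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        net = make_net(n, [])
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.45:
                    net.graph.add_edge(i, j, weight=float(rng.uniform(0.05, 2)),
                                       occupancy=1.0, correlation=0.5)
        if not nx.has_path(net.graph, 0, n - 1):
            with pytest.raises(NoPathError):
                optimal_path(net, PathQuery(0, n - 1))
            return
        oracle = enumerate_simple_paths(net.graph, 0, n - 1)
        tol = float(rng.uniform(0.1, 2.0))
        bound = oracle[0][0] + tol
        expected = [(w, p) for w, p in oracle if w <= bound + 1e-9]
        p = optimal_path(net, PathQuery(0, n - 1))
        assert p.weight == pytest.approx(oracle[0][0])
        assert p.nodes == oracle[0][1]
        ens = suboptimal_paths(net, PathQuery(0, n - 1, tolerance=tol))
        got = [(p.weight, p.nodes) for p in ens.paths]
        assert len(got) == len(expected)
        for (gw, gp), (ew, ep) in zip(got, expected):
            assert gw == pytest.approx(ew)
            assert gp == ep


class TestWindowedAnalysis:
    def test_uniform_partition_350ns(self):
        scheme = nd.WindowScheme.uniform(7, 3500)
        assert scheme.n_windows == 7
        assert all(b - a == 500 for a, b in scheme.ranges)
        assert scheme.ranges[0] == (0, 500)
        assert scheme.ranges[-1] == (3000, 3500)

    def test_single_window_reproduces_full_network(self, benchmark_trajectory):
        _, _, traj = benchmark_trajectory
        full = build_network_from_trajectory(traj, CA_PARAMS)
        one = windowed_networks(traj, 1, CA_PARAMS)[0].network
        assert nx.utils.graphs_equal(full.graph, one.graph)

    def test_stationary_model_same_path_every_window(self, benchmark_trajectory):
        _, path, traj = benchmark_trajectory
        q = PathQuery(path[0], path[-1], tolerance=0.0)
        results = windowed_networks(traj, 7, CA_PARAMS, q)
        assert len(results) == 7
        for r in results:
            assert r.ensemble.optimal.nodes == tuple(path)


class TestInterfaceEdges:
    def _two_chain_net(self):
        residues = tuple(("A", i, "") for i in range(1, 4)) \
            + tuple(("B", i, "") for i in range(1, 4))
        g = nx.Graph()
        g.add_nodes_from(range(6))
        corr = {(0, 3): 0.9, (1, 4): 0.8, (2, 5): 0.6, (0, 1): 0.7}
        for (i, j), c in corr.items():
            g.add_edge(i, j, weight=-math.log(c), occupancy=0.9,
                       correlation=c)
        return DynamicalNetwork(g, residues, NetworkParams())

    def test_single_group_empty(self):
        net = self._two_chain_net()
        df = interface_edge_summary(net, {"A": "g", "B": "g"})
        assert df.empty

    def test_cross_chain_rows_and_weights(self):
        net = self._two_chain_net()
        df = interface_edge_summary(net, {"A": "ras", "B": "raf"})
        assert len(df) == 3
        for _, row in df.iterrows():
            assert row["weight"] == pytest.approx(
                -math.log(abs(row["correlation"])))

    def test_unassigned_chain_is_error(self):
        net = self._two_chain_net()
        with pytest.raises(nd.errors.GroupingError):
            interface_edge_summary(net, {"A": "ras"})

    def test_edge_table_columns(self, benchmark_trajectory):
        _, _, traj = benchmark_trajectory
        net = build_network_from_trajectory(traj, CA_PARAMS)
        df = to_edge_table(net)
        assert list(df.columns) == ["node_i", "node_j", "occupancy",
                                    "correlation", "weight"]
        assert (df["weight"] >= 0).all()
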