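"""Tests of graph measures against closed forms and brute-force oracles."""

import numpy as np
import networkx as nx
import pytest

from cogconn import fixture_graph
from cogconn.connectome import BinaryGraph, WeightedConnectome
from cogconn.metrics import (
    MetricError,
    characteristic_path_length,
    global_efficiency,
    local_efficiency,
    maslov_sneppen_rewire,
    nodal_global_efficiency,
    nodal_local_efficiency,
    nodal_strength,
    average_strength,
    participation,
    shortest_path_lengths,
    small_worldness,
    transitivity,
)
from conftest import (
    bf_characteristic_path_length,
    bf_floyd_warshall,
    bf_global_efficiency,
    bf_local_efficiency,
    bf_nodal_global_efficiency,
    bf_participation,
    bf_transitivity,
    random_binary_graph,
)


class TestClosedForms:
    def test_transitivity_closed_forms(self):
        assert transitivity(fixture_graph("complete", 4)) == 1.0
        assert transitivity(fixture_graph("star", 5)) == 0.0
        assert transitivity(fixture_graph("k4_minus_edge", 4)) == 0.75

    def test_global_efficiency_closed_forms(self):
        assert global_efficiency(fixture_graph("complete", 5)) == 1.0
        assert global_efficiency(fixture_graph("path", 3)) == pytest.approx(5 / 6)

    def test_local_efficiency_closed_forms(self):
        assert local_efficiency(fixture_graph("complete", 4), "n0") == 1.0
        assert local_efficiency(fixture_graph("star", 5), "n0") == 0.0
        # in K4 minus edge (2,3), node 0's neighbours {1,2,3} form a path
        assert local_efficiency(fixture_graph("k4_minus_edge", 4), "n0") == pytest.approx(5 / 6)

    def test_isolated_node_has_zero_nodal_efficiency(self):
        adj = np.zeros((4, 4), dtype=np.uint8)
        adj[0, 1] = adj[1, 0] = 1
        g = BinaryGraph(adj, ("a", "b", "c", "d"))
        assert global_efficiency(g, "c") == 0.0
        assert local_efficiency(g, "c") == 0.0

    def test_shortest_paths_examples(self):
        d = shortest_path_lengths(fixture_graph("path", 3))
        assert d.loc["n0", "n2"] == 2
        k5 = shortest_path_lengths(fixture_graph("complete", 5))
        off = k5.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.all(off == 1)

    def test_unreachable_pairs_are_infinite(self):
        adj = np.zeros((3, 3), dtype=np.uint8)
        adj[0, 1] = adj[1, 0] = 1
        d = shortest_path_lengths(BinaryGraph(adj, ("a", "b", "c")))
        assert np.isinf(d.loc["a", "c"])

    def test_participation_closed_forms(self):
        g = fixture_graph("complete", 4)
        same = {l: "m1" for l in g.node_labels}
        assert np.all(participation(g, same) == 0.0)
        # degree-2 node with one edge in each of two modules
        p3 = fixture_graph("path", 3)
        comm = {"n0": "m1", "n1": "m1", "n2": "m2"}
        assert participation(p3, comm)["n1"] == pytest.approx(0.5)

    def test_participation_requires_full_assignment(self):
        g = fixture_graph("path", 3)
        with pytest.raises(MetricError):
            participation(g, {"n0": "m1", "n1": "m1"})

    def test_strength_closed_forms(self):
        n = 4
        m = np.full((n, n), 0.5)
        np.fill_diagonal(m, 0)
        w = WeightedConnectome(m, tuple("abcd"))
        assert np.all(nodal_strength(w) == 1.5)
        assert average_strength(w) == pytest.approx(1.5)

    def test_strength_signed_cancellation(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.4
        m[0, 2] = m[2, 0] = -0.4
        w = WeightedConnectome(m, ("a", "b", "c"))
        assert nodal_strength(w)["a"] == pytest.approx(0.0)
        assert nodal_strength(w, absolute=True)["a"] == pytest.approx(0.8)


class TestOracleEquivalence:
    def test_all_measures_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(100)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            g = random_binary_graph(rng, n, p=float(rng.uniform(0.2, 0.7)))
            adj = g.adjacency
            modules = rng.integers(0, 3, n)
            comm = {l: f"m{modules[i]}" for i, l in enumerate(g.node_labels)}
            assert global_efficiency(g) == pytest.approx(
                bf_global_efficiency(adj), abs=1e-12
            )
            np.testing.assert_allclose(
                nodal_global_efficiency(g), bf_nodal_global_efficiency(adj), atol=1e-12
            )
            assert transitivity(g) == pytest.approx(bf_transitivity(adj), abs=1e-12)
            np.testing.assert_allclose(
                nodal_local_efficiency(g), bf_local_efficiency(adj), atol=1e-12
            )
            np.testing.assert_allclose(
                participation(g, comm).to_numpy(),
                bf_participation(adj, modules),
                atol=1e-12,
            )

    def test_shortest_paths_match_floyd_warshall(self):
        rng = np.random.default_rng(101)
        for _ in range(20):
            g = random_binary_graph(rng, int(rng.integers(4, 13)))
            got = shortest_path_lengths(g).to_numpy()
            np.testing.assert_array_equal(got, bf_floyd_warshall(g.adjacency))

    def test_measures_match_networkx(self):
        rng = np.random.default_rng(102)
        for _ in range(30):
            g = random_binary_graph(rng, int(rng.integers(5, 13)))
            G = g.to_networkx()
            assert global_efficiency(g) == pytest.approx(
                nx.global_efficiency(G), abs=1e-12
            )
            assert transitivity(g) == pytest.approx(nx.transitivity(G), abs=1e-12)
            assert local_efficiency(g) == pytest.approx(
                nx.local_efficiency(G), abs=1e-12
            )

    def test_characteristic_path_length_matches_oracle(self):
        rng = np.random.default_rng(103)
        for _ in range(20):
            g = random_binary_graph(rng, int(rng.integers(4, 12)), p=0.3)
            assert characteristic_path_length(g) == pytest.approx(
                bf_characteristic_path_length(g.adjacency), abs=1e-12
            )


def bf_transitivity_nx(g: BinaryGraph) -> float:
    return nx.transitivity(g.to_networkx())


class TestInvariants:
    def test_permutation_invariance(self):
        rng = np.random.default_rng(104)
        for _ in range(10):
            n = 10
            g = random_binary_graph(rng, n)
            perm = rng.permutation(n)
            padj = g.adjacency[np.ix_(perm, perm)]
            pg = BinaryGraph(padj, tuple(np.array(g.node_labels)[perm]))
            assert transitivity(g) == pytest.approx(transitivity(pg), abs=1e-12)
            assert global_efficiency(g) == pytest.approx(
                global_efficiency(pg), abs=1e-12
            )
            assert local_efficiency(g) == pytest.approx(
                local_efficiency(pg), abs=1e-12
            )

    def test_measures_within_bounds(self):
        rng = np.random.default_rng(105)
        for _ in range(20):
            g = random_binary_graph(rng, 10)
            comm = {l: f"m{i % 4}" for i, l in enumerate(g.node_labels)}
            assert 0 <= global_efficiency(g) <= 1
            assert 0 <= transitivity(g) <= 1
            assert 0 <= local_efficiency(g) <= 1
            p = participation(g, comm)
            assert np.all((p >= 0) & (p < 1))

    def test_adding_edge_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(106)
        for _ in range(20):
            g = random_binary_graph(rng, 9, p=0.3)
            zeros = np.argwhere(np.triu(g.adjacency == 0, k=1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            adj = g.adjacency.copy()
            adj[i, j] = adj[j, i] = 1
            g2 = BinaryGraph(adj, g.node_labels)
            assert global_efficiency(g2) >= global_efficiency(g) - 1e-12


class TestSmallWorldness:
    def test_complete_graph_sigma_is_one(self):
        assert small_worldness(fixture_graph("complete", 8), n_random=10, seed=0) == 1.0

    def test_rewiring_preserves_degree_sequence(self):
        rng = np.random.default_rng(107)
        g = random_binary_graph(rng, 12, p=0.4)
        r = maslov_sneppen_rewire(g, np.random.default_rng(1))
        np.testing.assert_array_equal(
            np.sort(r.degrees()), np.sort(g.degrees())
        )
        assert r.n_edges == g.n_edges

    def test_ring_lattice_with_light_rewiring_is_small_world(self):
        # Watts-Strogatz regime: high clustering, short paths
        detections = 0
        n_seeds = 20
        for seed in range(n_seeds):
            G = nx.connected_watts_strogatz_graph(24, 4, 0.1, seed=seed)
            adj = nx.to_numpy_array(G, dtype=np.uint8)
            g = BinaryGraph(adj, tuple(f"n{i}" for i in range(24)))
            sigma = small_worldness(g, n_random=30, seed=seed)
            detections += sigma > 1
        assert detections >= int(0.9 * n_seeds)

    def test_dense_random_graph_sigma_near_one(self):
        sigmas = []
        for seed in range(10):
            G = nx.gnp_random_graph(24, 0.5, seed=seed)
            adj = nx.to_numpy_array(G, dtype=np.uint8)
            g = BinaryGraph(adj, tuple(f"n{i}" for i in range(24)))
            sigmas.append(small_worldness(g, n_random=30, seed=seed))
        assert all(0.8 <= s <= 1.2 for s in sigmas)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(108)
        g = random_binary_graph(rng, 16, p=0.3)
        a = small_worldness(g, n_random=20, seed=5)
        b = small_worldness(g, n_random=20, seed=5)
        assert a == b

    def test_too_sparse_graph_raises(self):
        adj = np.zeros((4, 4), dtype=np.uint8)
        adj[0, 1] = adj[1, 0] = 1
        with pytest.raises(MetricError):
            small_worldness(BinaryGraph(adj, tuple("abcd")), n_random=10, seed=0)
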