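"""Graph generators, randomizers and builders."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from netdyn import graphs
from netdyn.graphs import (
    GraphParameterError,
    RandomizationError,
    degree_sequence,
    edge_count,
    graph_from_stoichiometry,
    graph_from_weights,
    make_hierarchical,
    make_modular,
    make_standard,
    randomize_degree_preserving,
    rewire_one_endpoint,
)

from conftest import assert_simple_adjacency


class TestModular:
    def test_node_and_edge_count_conserved(self):
        # rewiring moves endpoints, never creates/destroys edges
        for seed in range(10):
            A = make_modular(4, 15, 0.23, seed=seed)
            assert_simple_adjacency(A)
            assert A.shape[0] == 60
            assert edge_count(A) == 420

    def test_no_rewiring_gives_disjoint_cliques(self):
        A = make_modular(4, 15, 0.0, seed=3)
        assert edge_count(A) == 420
        # each 15-block is internally complete, nothing between blocks
        for c in range(4):
            lo, hi = 15 * c, 15 * (c + 1)
            block = A[lo:hi, lo:hi]
            assert block.sum() == 15 * 14
        assert A.sum() == 4 * 15 * 14

    def test_full_rewiring_stays_simple(self):
        for seed in range(20):
            A = make_modular(2, 3, 1.0, seed=seed)
            assert_simple_adjacency(A)
            assert A.shape[0] == 6
            assert edge_count(A) == 6

    def test_parameter_validation(self):
        with pytest.raises(GraphParameterError):
            make_modular(1, 15, 0.2, seed=0)
        with pytest.raises(GraphParameterError):
            make_modular(4, 15, 1.5, seed=0)


class TestStandard:
    def test_erdos_renyi_mean_edge_count(self):
        # binomial mean p * C(60, 2) = 0.23 * 1770 = 407.1
        counts = [
            edge_count(make_standard("erdos_renyi", 60, seed=s, p=0.23))
            for s in range(150)
        ]
        assert np.mean(counts) == pytest.approx(407.1, rel=0.02)

    def test_barabasi_albert_edge_count(self):
        # growth from an m-node seedless core attaches m edges per new node
        A = make_standard("barabasi_albert", 60, seed=4, m=8)
        assert_simple_adjacency(A)
        assert edge_count(A) == (60 - 8) * 8 == 416

    def test_ring_lattice_regular(self):
        A = make_standard("watts_strogatz", 60, seed=5, ring_neighbors=14)
        assert edge_count(A) == 60 * 14 // 2 == 420
        assert (degree_sequence(A) == 14).all()

    def test_unknown_model_rejected(self):
        with pytest.raises(GraphParameterError):
            make_standard("configuration", 60, seed=0)
        with pytest.raises(GraphParameterError):
            make_standard("watts_strogatz", 60, seed=0, ring_neighbors=15)


class TestHierarchical:
    def test_printed_size_at_three_levels(self):
        A = make_hierarchical(3)
        assert A.shape[0] == 64
        assert edge_count(A) == 174

    def test_base_case_is_complete_module(self):
        A = make_hierarchical(1)
        assert A.shape[0] == 4
        assert edge_count(A) == 6
        assert (A + np.eye(4) == 1).all()

    def test_deterministic_and_connected(self):
        A1, A2 = make_hierarchical(3), make_hierarchical(3)
        assert np.array_equal(A1, A2)
        assert graphs.is_connected(A1)

    def test_edge_recursion(self):
        # E_k = 4 E_{k-1} + 3^k + 3
        assert edge_count(make_hierarchical(2)) == 4 * 6 + 9 + 3 == 36
        assert edge_count(make_hierarchical(3)) == 4 * 36 + 27 + 3 == 174


class TestDegreePreservingRandomization:
    def test_zero_swaps_identity(self, modular_graph):
        A = randomize_degree_preserving(modular_graph, 0, seed=0)
        assert np.array_equal(A, modular_graph)

    @pytest.mark.parametrize("n_swaps", [1, 50, 500])
    def test_degree_sequence_preserved(self, modular_graph, n_swaps):
        A = randomize_degree_preserving(modular_graph, n_swaps, seed=7)
        assert_simple_adjacency(A)
        assert np.array_equal(
            degree_sequence(A), degree_sequence(modular_graph)
        )
        assert edge_count(A) == edge_count(modular_graph)

    def test_input_not_modified(self, modular_graph):
        before = modular_graph.copy()
        randomize_degree_preserving(modular_graph, 100, seed=8)
        assert np.array_equal(modular_graph, before)

    def test_triangle_has_no_legal_swap(self):
        # every proposal on K3 creates a self-loop or multi-edge
        K3 = np.ones((3, 3), dtype=np.int8) - np.eye(3, dtype=np.int8)
        with pytest.raises(RandomizationError):
            randomize_degree_preserving(K3, 1, seed=0)


class TestRewireOneEndpoint:
    def test_zero_rewires_identity(self):
        A = make_standard("watts_strogatz", 60, seed=1, ring_neighbors=14)
        assert np.array_equal(rewire_one_endpoint(A, 0, seed=0), A)

    def test_edge_count_conserved(self):
        A = make_standard("watts_strogatz", 60, seed=1, ring_neighbors=14)
        B = rewire_one_endpoint(A, 420, seed=2)
        assert_simple_adjacency(B)
        assert edge_count(B) == 420

    def test_small_world_transition(self):
        # 10% rewiring: clustering drops below the lattice's, paths shorten
        A = make_standard("watts_strogatz", 60, seed=1, ring_neighbors=14)
        G0 = graphs.to_networkx(A)
        c0, l0 = nx.average_clustering(G0), nx.average_shortest_path_length(G0)
        cs, ls = [], []
        for seed in range(20):
            B = rewire_one_endpoint(A, 42, seed=seed)
            G = graphs.to_networkx(B)
            if not nx.is_connected(G):
                continue
            cs.append(nx.average_clustering(G))
            ls.append(nx.average_shortest_path_length(G))
        assert np.mean(cs) < c0
        assert np.mean(ls) < 0.9 * l0

    def test_complete_graph_rejected(self):
        K5 = np.ones((5, 5), dtype=np.int8) - np.eye(5, dtype=np.int8)
        with pytest.raises(RandomizationError):
            rewire_one_endpoint(K5, 1, seed=0)


class TestBuildersFromData:
    def test_single_reaction_links_metabolites(self):
        S = np.array([[-1.0], [1.0]])
        A = graph_from_stoichiometry(S)
        assert A.shape == (2, 2)
        assert edge_count(A) == 1

    def test_disjoint_reactions_stay_disconnected(self):
        S = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, -1.0], [0.0, 1.0]])
        A = graph_from_stoichiometry(S)
        assert A[0, 2] == A[0, 3] == A[1, 2] == A[1, 3] == 0
        assert A[0, 1] == 1 and A[2, 3] == 1

    def test_matches_naive_shared_reaction_oracle(self, rng):
        S = rng.choice([-1.0, 0.0, 0.0, 1.0], size=(10, 6))
        A = graph_from_stoichiometry(S)
        for i in range(10):
            for j in range(10):
                expected = int(i != j and np.dot(S[i], S[j]) != 0)
                assert A[i, j] == expected

    def test_weights_all_zero_empty_graph(self):
        A = graph_from_weights(np.zeros((5, 5)), threshold=-3, log10_transform=True)
        assert A.sum() == 0

    def test_weights_uniform_complete_graph(self):
        W = np.ones((5, 5))
        A = graph_from_weights(W, threshold=-3, log10_transform=True)
        assert edge_count(A) == 10

    def test_weights_symmetrization_oracle(self):
        # one passing direction per pair is enough for an edge
        W = np.array(
            [
                [0.0, 1.0, 1e-5, 1e-5],
                [1e-5, 0.0, 1.0, 1e-5],
                [1e-5, 1e-5, 0.0, 1.0],
                [1e-5, 1e-5, 1e-5, 0.0],
            ]
        )
        A = graph_from_weights(W, threshold=-3.0, log10_transform=True)
        expected = np.zeros((4, 4), dtype=int)
        for i in range(4):
            for j in range(4):
                if i != j and (np.log10(W[i, j]) > -3 or np.log10(W[j, i]) > -3):
                    expected[i, j] = 1
        assert np.array_equal(A, expected)


@settings(deadline=None, max_examples=25)
@given(
    n_swaps=st.integers(min_value=0, max_value=200),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_double_edge_swap_invariants(n_swaps, seed):
    """Degree sequence and simplicity survive any number of swaps."""
    A0 = make_modular(3, 6, 0.1, seed=0)
    A = randomize_degree_preserving(A0, n_swaps, seed=seed)
    assert_simple_adjacency(A)
    assert np.array_equal(degree_sequence(A), degree_sequence(A0))
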