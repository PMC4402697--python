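"""Core graph types: configuration probability, transitivity, closure."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigs.graph import (
    HaplotypeId,
    IBDConfiguration,
    ProbabilisticIBDGraph,
    clique_close,
    connected_components,
    edge_key,
    graph_probability,
    is_transitive,
    log_graph_probability,
)


def brute_probability(g: IBDConfiguration, G: ProbabilisticIBDGraph) -> float:
    """Direct product of induced edge probabilities (independent oracle)."""
    prod = 1.0
    n = len(g.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            p = G.probability(g.nodes[i], g.nodes[j])
            prod *= p if g.has_edge(g.nodes[i], g.nodes[j]) else 1.0 - p
    return prod


class TestHaplotypeId:
    def test_ordering_is_lexicographic(self):
        assert HaplotypeId("A", 2) < HaplotypeId("B", 1)
        assert HaplotypeId("A", 1) < HaplotypeId("A", 2)
        assert HaplotypeId("A", 1) == HaplotypeId("A", 1)

    def test_parse_round_trip(self):
        h = HaplotypeId("S001", 2)
        assert HaplotypeId.parse(str(h)) == h

    def test_edge_key_canonical(self):
        a, b = HaplotypeId("B", 1), HaplotypeId("A", 2)
        assert edge_key(a, b) == (b, a)
        with pytest.raises(ValueError):
            edge_key(a, a)


class TestGraphProbability:
    @pytest.mark.parametrize(
        "edges, expected",
        [
            ([(1, 2), (1, 3), (2, 3)], 0.081),  # full triangle
            ([(2, 3)], 0.001),  # only the weak edge
            ([], 0.009),  # empty graph
        ],
    )
    def test_worked_values(self, worked_graph, edges, expected):
        g = IBDConfiguration([1, 2, 3], edges)
        assert graph_probability(g, worked_graph) == pytest.approx(expected, abs=1e-12)

    def test_uniform_half_graph(self):
        G = ProbabilisticIBDGraph([1, 2, 3], {(1, 2): 0.5, (1, 3): 0.5, (2, 3): 0.5})
        for edges in ([], [(1, 2)], [(1, 2), (1, 3), (2, 3)]):
            g = IBDConfiguration([1, 2, 3], edges)
            assert graph_probability(g, G) == pytest.approx(0.125)

    @pytest.mark.parametrize("n", [3, 4])
    def test_normalizes_over_all_configurations(self, n, rng):
        """Edge indicators are independent, so the 2^m configuration
        probabilities must sum to one."""
        nodes = list(range(n))
        pairs = list(itertools.combinations(nodes, 2))
        probs = {e: rng.uniform(0.05, 0.95) for e in pairs}
        G = ProbabilisticIBDGraph(nodes, probs)
        total = 0.0
        for bits in itertools.product([0, 1], repeat=len(pairs)):
            edges = [e for e, b in zip(pairs, bits) if b]
            total += graph_probability(IBDConfiguration(nodes, edges), G)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_log_domain_matches_direct_product(self, rng):
        n = 8
        nodes = list(range(n))
        pairs = list(itertools.combinations(nodes, 2))
        for _ in range(5):
            G = ProbabilisticIBDGraph(nodes, {e: rng.uniform(0.01, 0.99) for e in pairs})
            edges = [e for e in pairs if rng.random() < 0.4]
            g = IBDConfiguration(nodes, edges)
            direct = brute_probability(g, G)
            assert graph_probability(g, G) == pytest.approx(direct, rel=1e-12)
            assert np.exp(log_graph_probability(g, G)) == pytest.approx(direct, rel=1e-12)

    def test_invariant_under_relabeling(self, rng):
        nodes = ["a", "b", "c", "d"]
        pairs = list(itertools.combinations(nodes, 2))
        probs = {e: rng.uniform(0.1, 0.9) for e in pairs}
        edges = [("a", "b"), ("c", "d")]
        p_ref = graph_probability(
            IBDConfiguration(nodes, edges), ProbabilisticIBDGraph(nodes, probs)
        )
        relabel = {"a": "w", "b": "x", "c": "y", "d": "z"}
        probs2 = {edge_key(relabel[a], relabel[b]): p for (a, b), p in probs.items()}
        edges2 = [(relabel[a], relabel[b]) for a, b in edges]
        p_new = graph_probability(
            IBDConfiguration(sorted(relabel.values()), edges2),
            ProbabilisticIBDGraph(sorted(relabel.values()), probs2),
        )
        assert p_new == pytest.approx(p_ref, rel=1e-12)

    def test_node_set_mismatch_raises(self, worked_graph):
        g = IBDConfiguration([1, 2, 4])
        with pytest.raises(ValueError, match="node set"):
            graph_probability(g, worked_graph)

    def test_degenerate_probability_conflicts(self):
        G = ProbabilisticIBDGraph([1, 2], matrix=np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            graph_probability(IBDConfiguration([1, 2]), G)
        # consistent assignment is fine: certain edge present
        assert graph_probability(IBDConfiguration([1, 2], [(1, 2)]), G) == 1.0


class TestTransitivity:
    def test_triangle_is_transitive(self):
        g = IBDConfiguration([1, 2, 3], [(1, 2), (1, 3), (2, 3)])
        assert is_transitive(g)

    def test_open_wedge_is_not(self):
        g = IBDConfiguration([1, 2, 3], [(1, 2), (1, 3)])
        assert not is_transitive(g)

    def test_empty_graph_is_transitive(self):
        assert is_transitive(IBDConfiguration([1, 2, 3]))

    def test_components(self):
        g = IBDConfiguration([1, 2, 3], [(1, 2)])
        assert connected_components(g) == [(1, 2), (3,)]
        assert connected_components(IBDConfiguration([1, 2, 3, 4])) == [
            (1,), (2,), (3,), (4,)
        ]
        assert connected_components(IBDConfiguration([1, 2, 3], [(1, 2), (2, 3)])) == [
            (1, 2, 3)
        ]

    def test_clique_close_triangle(self):
        g = IBDConfiguration([1, 2, 3], [(1, 2), (2, 3)])
        closed = clique_close(g)
        assert closed.edges() == frozenset({(1, 2), (2, 3), (1, 3)})

    def test_clique_close_idempotent_on_clique(self):
        g = IBDConfiguration([1, 2, 3], [(1, 2), (1, 3), (2, 3)])
        assert clique_close(g) == g

    def test_clique_close_respects_components(self):
        g = IBDConfiguration([1, 2, 3, 4, 5], [(1, 2), (3, 4), (4, 5)])
        closed = clique_close(g)
        assert closed.edges() == frozenset({(1, 2), (3, 4), (4, 5), (3, 5)})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 6), st.integers(0, 6)), max_size=15))
    def test_closure_always_transitive_and_monotone(self, raw_edges):
        edges = [(a, b) for a, b in raw_edges if a != b]
        g = IBDConfiguration(range(7), edges)
        closed = g.clique_close()
        assert closed.is_transitive()
        assert g.edges() <= closed.edges()
        assert closed.clique_close() == closed

    def test_from_partition(self):
        g = IBDConfiguration.from_partition([1, 2, 3, 4], [[1, 3], [2], [4]])
        assert g.is_transitive()
        assert g.edges() == frozenset({(1, 3)})
        with pytest.raises(ValueError):
            IBDConfiguration.from_partition([1, 2], [[1], [1, 2]])


class TestProbabilisticGraph:
    def test_uncalled_pairs_carry_epsilon(self):
        G = ProbabilisticIBDGraph([1, 2, 3], {(1, 2): 0.8}, epsilon=0.0046)
        assert G.probability(1, 3) == 0.0046
        assert G.probability(2, 3) == 0.0046
        assert G.probability(2, 1) == 0.8  # symmetric access

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ProbabilisticIBDGraph([1, 2], {(1, 2): 1.5})

    def test_rejects_asymmetric_matrix(self):
        M = np.array([[0.0, 0.2], [0.7, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ProbabilisticIBDGraph([1, 2], matrix=M)

    def test_subgraph(self):
        G = ProbabilisticIBDGraph([1, 2, 3], {(1, 2): 0.8, (2, 3): 0.3})
        sub = G.subgraph([2, 3])
        assert sub.probability(2, 3) == 0.3
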