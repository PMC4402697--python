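"""Monte-Carlo sampler: weights, repairs, accumulation, convergence."""

import numpy as np
import pytest

from pigs.exact import exact_conditionals
from pigs.graph import IBDConfiguration, ProbabilisticIBDGraph
from pigs.sampler import (
    SamplerConfig,
    WeightParams,
    edge_weight,
    initialize_configuration,
    repair_after_add,
    repair_after_remove,
    run_sampler,
)
from pigs.synthetic import random_probabilistic_graph


class TestEdgeWeight:
    def test_peak_at_half(self):
        assert edge_weight(0.5) == pytest.approx(0.5)

    def test_high_probability_edge_rarely_selected(self):
        # 1 - Phi((0.9 - 0.5) / 0.234), evaluated independently
        assert edge_weight(0.9) == pytest.approx(0.0436883, abs=1e-6)

    def test_symmetric_about_half(self):
        assert edge_weight(0.1) == pytest.approx(edge_weight(0.9), abs=1e-12)
        for p in (0.2, 0.35, 0.45):
            assert edge_weight(p) == pytest.approx(edge_weight(1 - p), abs=1e-12)

    def test_strictly_positive_inside_unit_interval(self):
        w = edge_weight(np.linspace(0.001, 0.999, 50))
        assert np.all(w > 0)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            WeightParams(sigma=0.0)


class TestInitialization:
    def test_closure_forces_low_probability_edge(self):
        G = ProbabilisticIBDGraph(
            [1, 2, 3], {(1, 2): 0.995, (2, 3): 0.999, (1, 3): 0.0046}
        )
        g = initialize_configuration(G)
        assert g.edges() == frozenset({(1, 2), (2, 3), (1, 3)})

    def test_all_below_threshold_gives_empty(self):
        G = ProbabilisticIBDGraph([1, 2, 3], {(1, 2): 0.9, (2, 3): 0.98})
        assert initialize_configuration(G).n_edges == 0

    def test_all_pinned_gives_complete_clique(self):
        G = ProbabilisticIBDGraph(
            [1, 2, 3], {(1, 2): 0.99, (1, 3): 0.995, (2, 3): 0.999}
        )
        assert initialize_configuration(G).n_edges == 3


class TestRepairAfterAdd:
    def test_merging_two_cliques(self):
        g = IBDConfiguration([1, 2, 3, 4], [(1, 2), (3, 4)])
        repaired = repair_after_add(g, (2, 3))
        assert repaired.n_edges == 6  # single 4-clique

    def test_add_inside_clique_is_noop(self):
        g = IBDConfiguration([1, 2, 3], [(1, 2), (1, 3), (2, 3)])
        assert repair_after_add(g, (1, 2)) == g

    def test_add_between_singletons(self):
        g = IBDConfiguration([1, 2, 3])
        repaired = repair_after_add(g, (1, 2))
        assert repaired.edges() == frozenset({(1, 2)})


class TestRepairAfterRemove:
    def test_weak_node_follows_strong_side(self, worked_graph):
        g = IBDConfiguration([1, 2, 3], [(1, 2), (1, 3), (2, 3)])
        repaired = repair_after_remove(g, worked_graph, (1, 3), rng=0)
        # node 2 joins node 1's side: p12 = 0.9 beats p23 = 0.1
        assert repaired.connected_components() == [(1, 2), (3,)]
        assert repaired.is_transitive()

    def test_removing_only_edge_gives_singletons(self):
        G = ProbabilisticIBDGraph([1, 2], {(1, 2): 0.5})
        g = IBDConfiguration([1, 2], [(1, 2)])
        repaired = repair_after_remove(g, G, (1, 2), rng=0)
        assert repaired.n_edges == 0

    def test_pinned_subclique_survives_as_block(self):
        # 1-2 pinned; removing 3-4 must not break the 1-2 clique
        G = ProbabilisticIBDGraph(
            [1, 2, 3, 4],
            {(1, 2): 0.999, (1, 3): 0.6, (2, 3): 0.6, (3, 4): 0.5, (1, 4): 0.1, (2, 4): 0.1},
        )
        g = IBDConfiguration([1, 2, 3, 4], [(i, j) for i in range(1, 4) for j in range(i + 1, 5)])
        repaired = repair_after_remove(g, G, (3, 4), rng=1)
        assert repaired.is_transitive()
        assert repaired.has_edge(1, 2)  # pinned pair stays together
        assert not repaired.has_edge(3, 4)

    def test_missing_edge_is_contract_violation(self, worked_graph):
        g = IBDConfiguration([1, 2, 3], [(1, 2)])
        with pytest.raises(ValueError, match="not present"):
            repair_after_remove(g, worked_graph, (1, 3), rng=0)


class TestRunSampler:
    def test_worked_example_converges_to_exact(self, worked_graph):
        cfg = SamplerConfig(seed=11, max_iterations=5000, max_seconds=None)
        result, state = run_sampler(worked_graph, cfg)
        assert result[(2, 3)] == pytest.approx(0.324, rel=0.01)
        assert state.iteration == 5000

    def test_all_pinned_short_circuits(self):
        G = ProbabilisticIBDGraph(
            [1, 2, 3], {(1, 2): 0.995, (1, 3): 0.999, (2, 3): 0.999}
        )
        result, state = run_sampler(G, SamplerConfig(seed=0))
        assert all(v == 1.0 for v in result.values())
        assert state.converged
        assert state.iteration == 0

    def test_trivial_graphs(self):
        result, state = run_sampler(
            ProbabilisticIBDGraph([], {}), SamplerConfig(seed=0)
        )
        assert result == {} and state.converged

    def test_estimates_stay_in_unit_interval_and_accumulators_consistent(self):
        G = random_probabilistic_graph(6, seed=3)
        cfg = SamplerConfig(seed=3, max_iterations=500, max_seconds=None)
        result, state = run_sampler(G, cfg)
        for e, p in result.items():
            assert 0.0 <= p <= 1.0
            assert 0.0 <= state.n_ij[e] <= state.n_g
            assert p == pytest.approx(state.n_ij[e] / state.n_g)

    def test_every_visited_configuration_is_transitive(self):
        G = random_probabilistic_graph(6, seed=5)
        seen = []

        def check(iteration, labels, p_hat):
            seen.append(iteration)
            cfg = IBDConfiguration.from_labels(G.nodes, labels)
            assert cfg.is_transitive()

        run_sampler(
            G,
            SamplerConfig(seed=5, max_iterations=300, max_seconds=None),
            callback=check,
        )
        assert len(seen) == 300

    def test_bit_identical_under_same_seed(self):
        G = random_probabilistic_graph(7, seed=9)
        cfg = SamplerConfig(seed=42, max_iterations=2000, max_seconds=None)
        r1, s1 = run_sampler(G, cfg)
        r2, s2 = run_sampler(G, cfg)
        assert r1 == r2
        assert s1.n_g == s2.n_g
        assert s1.n_ij == s2.n_ij

    def test_timeout_flag(self):
        G = random_probabilistic_graph(6, seed=1)
        _, state = run_sampler(G, SamplerConfig(seed=1, max_seconds=0.0))
        assert state.timed_out

    def test_checkpoints_recorded(self):
        G = random_probabilistic_graph(5, seed=2)
        cfg = SamplerConfig(seed=2, max_iterations=200, max_seconds=None)
        _, state = run_sampler(G, cfg, checkpoints=(50, 200))
        assert set(state.checkpoints) == {50, 200}
        assert len(state.checkpoints[50]) == 10

    def test_small_graph_reaches_convergence_criterion(self, worked_graph):
        cfg = SamplerConfig(seed=4, max_seconds=None, max_iterations=None)
        _, state = run_sampler(worked_graph, cfg)
        assert state.converged
        assert state.stable_count >= cfg.convergence_window

    def test_five_node_accuracy_against_oracle(self):
        """Mean relative error vs exact conditionals <= 1% at 5000
        iterations, averaged over 25 seeded runs."""
        G = random_probabilistic_graph(5, seed=77)
        exact = {e: c.p_dot for e, c in exact_conditionals(G).items()}
        errs = []
        for r in range(25):
            cfg = SamplerConfig(seed=1000 + r, max_iterations=5000, max_seconds=None)
            result, _ = run_sampler(G, cfg)
            errs.append(
                np.mean([abs(exact[e] - result[e]) / exact[e] for e in exact])
            )
        assert np.mean(errs) <= 0.01

    def test_pinned_edges_report_one(self):
        G = ProbabilisticIBDGraph(
            [1, 2, 3, 4],
            {(1, 2): 0.999, (1, 3): 0.4, (2, 3): 0.6, (1, 4): 0.2, (2, 4): 0.3, (3, 4): 0.5},
        )
        result, _ = run_sampler(
            G, SamplerConfig(seed=6, max_iterations=2000, max_seconds=None)
        )
        assert result[(1, 2)] == 1.0
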