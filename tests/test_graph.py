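from itertools import combinations

import numpy as np
import pytest

from conftest import random_connectivity
from oracles import (
    betweenness_brute,
    global_efficiency_brute,
    local_efficiency_brute,
    nodal_efficiency_brute,
)

from attnet.connectivity import ConnectivityMatrix
from attnet.graph import (
    BinaryGraph,
    betweenness_centrality,
    degree,
    fit_truncated_power_law,
    global_efficiency,
    local_efficiency,
    matched_random_graph,
    matched_regular_graph,
    nodal_efficiency,
    small_world_regime,
    threshold_at_cost,
)
from attnet.synthetic import connectivity_from_graph, generate_benchmark_graph


def graph_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        adj[i, j] = adj[j, i] = True
    return BinaryGraph([f"n{i}" for i in range(n)], adj)


class TestThresholdAtCost:
    def test_cost_one_gives_complete_graph(self):
        conn = random_connectivity(6, 0)
        g = threshold_at_cost(conn, 1.0)
        assert g.n_edges == 15

    def test_keeps_strongest_entries(self):
        conn = random_connectivity(5, 3)
        g = threshold_at_cost(conn, 0.4)  # K = round(0.4 * 10) = 4
        assert g.n_edges == 4
        kept = np.array([conn.values[i, j] for i, j in g.edges()])
        dropped = np.setdiff1d(conn.upper_values(), kept)
        assert kept.min() >= dropped.max()
        np.testing.assert_allclose(np.sort(kept), np.sort(conn.upper_values())[-4:])

    def test_68_nodes_at_cost_point_one(self, rng):
        conn = random_connectivity(68, 5)
        g = threshold_at_cost(conn, 0.1)
        assert g.n_edges == 228  # round(0.1 * 2278)

    def test_edge_sets_nest_across_costs(self):
        conn = random_connectivity(12, 9)
        prev = set()
        for cost in (0.1, 0.2, 0.35, 0.6, 0.9):
            edges = set(threshold_at_cost(conn, cost).edges())
            assert prev <= edges
            prev = edges

    def test_undefined_entries_in_top_k_raise(self):
        vals = np.full((4, 4), 0.2)
        np.fill_diagonal(vals, np.nan)
        vals[0, 1] = vals[1, 0] = np.nan
        conn = ConnectivityMatrix([f"n{i}" for i in range(4)], vals)
        with pytest.raises(ValueError, match="undefined"):
            threshold_at_cost(conn, 1.0)

    def test_resulting_cost_matches_rounding_rule(self):
        conn = random_connectivity(10, 2)
        g = threshold_at_cost(conn, 0.3)
        assert g.n_edges == round(0.3 * 45)


class TestEfficiencyExamples:
    def test_complete_graph_unit_global_efficiency(self):
        g = graph_from_edges(4, list(combinations(range(4), 2)))
        assert global_efficiency(g) == pytest.approx(1.0)

    def test_three_node_path(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert global_efficiency(g) == pytest.approx(5 / 6)

    def test_empty_graph_zero(self):
        g = graph_from_edges(5, [])
        assert global_efficiency(g) == 0.0

    def test_triangle_local_efficiency_one(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert local_efficiency(g) == pytest.approx(1.0)

    def test_tree_local_efficiency_zero(self):
        g = graph_from_edges(6, [(0, 1), (0, 2), (1, 3), (1, 4), (2, 5)])
        assert local_efficiency(g) == 0.0

    def test_ring_c10_local_efficiency_zero(self):
        g = generate_benchmark_graph("ring_lattice", 10, 2, seed=0)
        assert local_efficiency(g) == 0.0

    def test_star_nodal_efficiencies(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        e = nodal_efficiency(g)
        assert e[0] == pytest.approx(1.0)
        np.testing.assert_allclose(e[1:], 2 / 3)

    def test_isolated_node_zero_nodal(self):
        g = graph_from_edges(4, [(0, 1), (0, 2)])
        assert nodal_efficiency(g)[3] == 0.0

    def test_path_middle_betweenness_one(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        bc = betweenness_centrality(g)
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_star_center_betweenness_one(self):
        g = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        bc = betweenness_centrality(g)
        assert bc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_edge_addition_never_decreases_global_efficiency(self, rng):
        conn = random_connectivity(10, 4)
        prev = -1.0
        for cost in np.linspace(0.05, 1.0, 12):
            e = global_efficiency(threshold_at_cost(conn, cost))
            assert e >= prev - 1e-12
            prev = e


class TestNullModels:
    def test_random_null_preserves_degree_sequence(self, rng):
        g = generate_benchmark_graph("watts_strogatz", 40, 6, 0.2, seed=1)
        null = matched_random_graph(g, seed=5)
        np.testing.assert_array_equal(
            np.sort(null.degree_sequence()), np.sort(g.degree_sequence())
        )
        assert null.n_edges == g.n_edges

    def test_regular_null_of_ten_nodes_ten_edges(self):
        g = generate_benchmark_graph("erdos_renyi", 10, 2, seed=2)
        assert g.n_edges == 10
        reg = matched_regular_graph(g)
        np.testing.assert_array_equal(reg.degree_sequence(), 2)
        assert reg.n_edges == 10

    def test_regular_null_preserves_n_and_k(self, rng):
        g = generate_benchmark_graph("erdos_renyi", 17, 4, seed=3)
        reg = matched_regular_graph(g)
        assert (reg.n_nodes, reg.n_edges) == (g.n_nodes, g.n_edges)

    def test_rewiring_lattice_raises_global_lowers_local(self):
        lattice = generate_benchmark_graph("ring_lattice", 60, 6, seed=0)
        null = matched_random_graph(lattice, seed=9)
        assert global_efficiency(null) > global_efficiency(lattice)
        assert local_efficiency(null) < local_efficiency(lattice)


class TestSmallWorldRegime:
    def test_single_point_grid_gives_point_interval(self):
        ws = generate_benchmark_graph("watts_strogatz", 60, 6, 0.1, seed=4)
        conn = connectivity_from_graph(ws, seed=0)
        regime = small_world_regime(conn, np.array([0.1]), n_null=5, seed=1)
        if regime.passes[0]:
            assert (regime.lo, regime.hi) == (0.1, 0.1)
        else:
            assert regime.empty

    def test_watts_strogatz_passes_at_its_own_cost(self):
        ws = generate_benchmark_graph("watts_strogatz", 100, 6, 0.1, seed=3)
        conn = connectivity_from_graph(ws, seed=1)
        grid = np.array([ws.cost])  # the graph itself is recovered here
        regime = small_world_regime(conn, grid, n_null=10, seed=2)
        assert not regime.empty


class TestTruncatedPowerLawFit:
    @staticmethod
    def sample(alpha, kc, n, seed, kmax=200):
        rng = np.random.default_rng(seed)
        k = np.arange(1, kmax + 1)
        pmf = k ** (alpha - 1.0) * np.exp(-k / kc)
        pmf = pmf / pmf.sum()
        return rng.choice(k, size=n, p=pmf)

    def test_parameter_recovery(self):
        samples = self.sample(1.6, 5.0, 5000, seed=0)
        fit = fit_truncated_power_law(samples, k_max=200)
        assert fit.converged
        assert fit.alpha == pytest.approx(1.6, abs=0.15)
        assert fit.kc == pytest.approx(5.0, rel=0.2)

    def test_pure_exponential_recovers_alpha_one(self):
        samples = self.sample(1.0, 4.0, 8000, seed=1)
        fit = fit_truncated_power_law(samples, k_max=200)
        assert fit.alpha == pytest.approx(1.0, abs=0.15)

    def test_degenerate_input_flagged_not_raised(self):
        fit = fit_truncated_power_law(np.full(20, 4))
        assert not fit.converged
        assert "degenerate" in fit.message

    def test_mle_and_ccdf_variants_agree_roughly(self):
        samples = self.sample(1.6, 5.0, 5000, seed=2)
        mle = fit_truncated_power_law(samples, k_max=200)
        lsq = fit_truncated_power_law(samples, k_max=200, method="ccdf_ls")
        assert mle.alpha == pytest.approx(lsq.alpha, abs=0.3)

    def test_too_few_degrees_rejected(self):
        with pytest.raises(ValueError):
            fit_truncated_power_law(np.array([1, 2, 3]))


class TestOracleAgreementSmall:
    """Spot agreement with brute force; the exhaustive sweep lives in acceptance."""

    def test_random_graphs_match_all_oracles(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            p = rng.uniform(0.2, 0.8)
            adj = rng.random((n, n)) < p
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            g = BinaryGraph([f"n{i}" for i in range(n)], adj)
            assert global_efficiency(g) == pytest.approx(
                global_efficiency_brute(adj), abs=1e-10
            )
            assert local_efficiency(g) == pytest.approx(
                local_efficiency_brute(adj), abs=1e-10
            )
            np.testing.assert_allclose(
                nodal_efficiency(g), nodal_efficiency_brute(adj), atol=1e-10
            )
            np.testing.assert_allclose(
                betweenness_centrality(g), betweenness_brute(adj), atol=1e-10
            )
            np.testing.assert_array_equal(degree(g), adj.sum(axis=1))
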