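"""Weighted graph metrics against hand values and exhaustive oracles."""

import networkx as nx
import numpy as np
import pytest

from conftest import local_efficiency_oracle, path_metrics_oracle, make_cohort
from faconn import (
    METRIC_COLUMNS,
    average_strength,
    clustering_coefficient,
    compute_metric_suite,
    local_efficiency,
    modularity,
    shortest_path_metrics,
    small_world_propensity,
)
from faconn.metrics import modularity_q


def sym(edges, n):
    w = np.zeros((n, n))
    for i, j, v in edges:
        w[i, j] = w[j, i] = v
    return w


class TestAverageStrength:
    def test_complete_unit_k4(self):
        assert average_strength(sym([(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)], 4)) == 3.0

    def test_path_graph_hand_sum(self):
        w = sym([(0, 1, 0.2), (1, 2, 0.4)], 3)
        assert average_strength(w) == pytest.approx(0.4)

    def test_empty_graph(self):
        assert average_strength(np.zeros((3, 3))) == 0.0


class TestShortestPaths:
    def test_single_edge_inverse_weight(self):
        cpl, eglob = shortest_path_metrics(sym([(0, 1, 0.5)], 2))
        assert cpl == pytest.approx(2.0)
        assert eglob == pytest.approx(0.5)

    def test_triangle_two_hop_shortcut(self):
        w = sym([(0, 1, 0.5), (1, 2, 0.5), (0, 2, 0.1)], 3)
        # d(0,2) = min(10, 2+2) = 4 via the two-hop route
        cpl, eglob = shortest_path_metrics(w)
        o_cpl, o_eglob = path_metrics_oracle(w)
        assert cpl == pytest.approx(o_cpl, abs=1e-12)
        assert eglob == pytest.approx(o_eglob, abs=1e-12)
        assert cpl == pytest.approx((2 + 2 + 4) / 3)

    def test_complete_unit_graph(self):
        w = sym([(i, j, 1.0) for i in range(5) for j in range(i + 1, 5)], 5)
        cpl, eglob = shortest_path_metrics(w)
        assert cpl == pytest.approx(1.0)
        assert eglob == pytest.approx(1.0)

    def test_disconnected_pair_excluded_from_cpl(self):
        w = sym([(0, 1, 0.5)], 3)  # node 2 isolated
        cpl, eglob = shortest_path_metrics(w)
        assert cpl == pytest.approx(2.0)
        assert eglob == pytest.approx((0.5 + 0.5) / 6)


class TestClustering:
    def test_unit_triangle(self):
        assert clustering_coefficient(sym([(0, 1, 1), (1, 2, 1), (0, 2, 1)], 3)) == pytest.approx(1.0)

    def test_star_has_no_triangles(self):
        w = sym([(0, k, 0.8) for k in range(1, 5)], 5)
        assert clustering_coefficient(w) == 0.0

    def test_weighted_triangle_onnela_hand_value(self):
        w = sym([(0, 1, 1.0), (1, 2, 0.5), (0, 2, 0.5)], 3)
        expected = (1.0 * 0.5 * 0.5) ** (1 / 3)
        assert clustering_coefficient(w) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.62996, abs=1e-5)


class TestLocalEfficiency:
    def test_complete_unit_k4(self):
        w = sym([(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)], 4)
        assert local_efficiency(w) == pytest.approx(1.0)

    def test_path_graph_is_zero(self):
        assert local_efficiency(sym([(0, 1, 0.5), (1, 2, 0.5)], 3)) == 0.0

    def test_four_node_toy_matches_subgraph_oracle(self):
        w = sym([(0, 1, 0.9), (0, 2, 0.4), (1, 2, 0.6), (2, 3, 0.8)], 4)
        assert local_efficiency(w) == pytest.approx(local_efficiency_oracle(w), abs=1e-12)


def test_oracle_equivalence_on_random_small_graphs():
    """Path metrics and local efficiency vs exhaustive enumeration, <=6 nodes."""
    rng = np.random.default_rng(0)
    for trial in range(200):
        n = int(rng.integers(2, 7))
        w = np.triu(rng.uniform(0, 1, (n, n)), 1)
        w[rng.random((n, n)) < 0.4] = 0.0  # sparsify
        w = np.triu(w, 1)
        w = w + w.T
        cpl, eglob = shortest_path_metrics(w)
        o_cpl, o_eglob = path_metrics_oracle(w)
        if np.isfinite(o_cpl):
            assert cpl == pytest.approx(o_cpl, abs=1e-10)
        assert eglob == pytest.approx(o_eglob, abs=1e-10)
        assert local_efficiency(w) == pytest.approx(
            local_efficiency_oracle(w), abs=1e-10
        )


def test_uniform_weight_scaling_laws():
    rng = np.random.default_rng(1)
    w = np.triu(rng.uniform(0.1, 1.0, (8, 8)), 1)
    w = w + w.T
    np.fill_diagonal(w, 0)
    c = 0.37
    assert clustering_coefficient(c * w) == pytest.approx(clustering_coefficient(w), abs=1e-12)
    assert average_strength(c * w) == pytest.approx(c * average_strength(w), abs=1e-12)
    cpl, eglob = shortest_path_metrics(w)
    cpl_s, eglob_s = shortest_path_metrics(c * w)
    assert cpl_s == pytest.approx(cpl / c, abs=1e-10)
    assert eglob_s == pytest.approx(c * eglob, abs=1e-10)


class TestModularity:
    def test_two_disjoint_triangles(self):
        w = sym([(0, 1, 1), (1, 2, 1), (0, 2, 1), (3, 4, 1), (4, 5, 1), (3, 5, 1)], 6)
        q, part = modularity(w, seed=0, n_restarts=10)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert sorted(sorted(p) for p in part) == [[0, 1, 2], [3, 4, 5]]

    def test_complete_graph_single_community(self):
        w = sym([(i, j, 1.0) for i in range(5) for j in range(i + 1, 5)], 5)
        q, part = modularity(w, seed=0, n_restarts=10)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(part) == 1

    def test_returned_q_equals_direct_evaluation(self, null_cohort):
        cohort, _ = null_cohort
        w = cohort.connectomes[0].weights
        q, part = modularity(w, seed=3, n_restarts=5)
        assert q == pytest.approx(modularity_q(w, part), abs=1e-12)
        g = nx.from_numpy_array(w)
        assert q == pytest.approx(
            nx.community.modularity(g, part, weight="weight"), abs=1e-9
        )

    def test_fixed_seed_reproduces_partition(self):
        rng = np.random.default_rng(5)
        w = np.triu(rng.uniform(0, 0.8, (20, 20)), 1)
        w[w < 0.4] = 0
        w = w + w.T
        q1, p1 = modularity(w, seed=11, n_restarts=20)
        q2, p2 = modularity(w, seed=11, n_restarts=20)
        assert q1 == q2
        assert p1 == p2

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError):
            modularity(np.zeros((4, 4)))


class TestSmallWorldPropensity:
    def test_watts_strogatz_regime_scores_high(self):
        hits = 0
        for seed in range(10):
            g = nx.watts_strogatz_graph(60, 6, 0.1, seed=seed)
            rng = np.random.default_rng(seed)
            w = np.zeros((60, 60))
            for i, j in g.edges:
                w[i, j] = w[j, i] = rng.uniform(0.5, 1.0)
            if small_world_propensity(w, n_null=10, seed=seed) > 0.6:
                hits += 1
        assert hits >= 8

    def test_lattice_itself_scores_low_on_path_length(self):
        # a pure ring lattice matches the lattice null in clustering but
        # has lattice-like long paths, so phi is pulled well below 1
        g = nx.watts_strogatz_graph(40, 4, 0.0, seed=0)
        w = np.zeros((40, 40))
        for i, j in g.edges:
            w[i, j] = w[j, i] = 0.7
        phi = small_world_propensity(w, n_null=10, seed=0)
        assert phi < 0.5

    def test_deterministic_under_seed(self, null_cohort):
        cohort, _ = null_cohort
        w = cohort.connectomes[0].weights
        assert small_world_propensity(w, n_null=3, seed=2) == small_world_propensity(
            w, n_null=3, seed=2
        )

    def test_bounded_in_unit_interval(self, null_cohort):
        cohort, _ = null_cohort
        for conn in cohort.connectomes[:3]:
            phi = small_world_propensity(conn, n_null=3, seed=0)
            assert 0.0 <= phi <= 1.0


class TestMetricSuite:
    def test_identical_connectomes_give_identical_rows(self):
        w = sym([(0, 1, 0.5), (1, 2, 0.4), (0, 2, 0.6), (2, 3, 0.3)], 4)
        cohort = make_cohort([w] * 6, ["case"] * 3 + ["control"] * 3)
        table = compute_metric_suite(cohort, n_restarts=5, swp_nulls=3, seed=0)
        assert list(table.columns) == list(METRIC_COLUMNS)
        deduped = table.drop_duplicates()
        assert len(deduped) == 1

    def test_deterministic_under_seed(self):
        w = sym([(0, 1, 0.5), (1, 2, 0.4), (0, 2, 0.6)], 3)
        cohort = make_cohort([w] * 6, ["case"] * 3 + ["control"] * 3)
        a = compute_metric_suite(cohort, n_restarts=3, swp_nulls=2, seed=7)
        b = compute_metric_suite(cohort, n_restarts=3, swp_nulls=2, seed=7)
        assert a.equals(b)
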