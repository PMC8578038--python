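"""Network-based statistic: edge GLM, components, permutation inference."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_cohort
from faconn import (
    CohortConfig,
    NBSInteraction,
    f_threshold,
    generate_cohort,
    jaccard_edges,
    planted_subnetwork,
    supra_threshold_components,
)
from faconn.nbs import EdgeStatMap, edge_interaction_fstats


class TestFThreshold:
    def test_printed_critical_value(self):
        assert f_threshold(1, 52, 0.01) == pytest.approx(7.1488, abs=1e-4)

    def test_large_df2_approaches_chi_square_limit(self):
        assert f_threshold(1, 10**7, 0.05) == pytest.approx(3.8415, abs=1e-3)

    def test_round_trip_with_survival_function(self):
        val = f_threshold(1, 52, 0.01)
        assert sps.f.sf(val, 1, 52) == pytest.approx(0.01, abs=1e-6)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            f_threshold(0, 10, 0.05)
        with pytest.raises(ValueError):
            f_threshold(1, 10, 1.5)


def _hand_cohort(y_edge, scores, groups, ages, sexes):
    """Cohort with one tested edge (0,1) carrying the weights y_edge."""
    n = len(y_edge)
    w = np.zeros((n, 3, 3))
    w[:, 0, 1] = w[:, 1, 0] = y_edge
    w[:, 0, 2] = w[:, 2, 0] = 0.5  # second always-present edge
    return make_cohort(w, groups, scores=scores, ages=ages, sexes=sexes)


class TestEdgeFStats:
    def setup_method(self):
        rng = np.random.default_rng(10)
        self.n = 12
        self.groups = ["case"] * 6 + ["control"] * 6
        self.scores = np.array([4, 7, 9, 10, 12, 15, 5, 8, 9, 11, 13, 16.0])
        self.ages = rng.uniform(6, 8, self.n)
        self.sexes = np.array([0, 1] * 6)
        g = np.array([1.0] * 6 + [0.0] * 6)
        self.y = 0.4 + 0.008 * g * (self.scores - 10) + rng.normal(0, 0.02, self.n)

    def _oracle_f(self):
        """Explicit RSS arithmetic via two separate least-squares fits."""
        g = np.array([1.0] * 6 + [0.0] * 6)
        full = np.column_stack(
            [np.ones(self.n), g, self.scores, g * self.scores, self.ages, self.sexes]
        )
        red = np.delete(full, 3, axis=1)
        rss = []
        for design in (full, red):
            beta, *_ = np.linalg.lstsq(design, self.y, rcond=None)
            resid = self.y - design @ beta
            rss.append(float(resid @ resid))
        rss_full, rss_red = rss
        return ((rss_red - rss_full) / 1.0) / (rss_full / (self.n - full.shape[1]))

    def test_matches_explicit_rss_arithmetic(self):
        cohort = _hand_cohort(self.y, self.scores, self.groups, self.ages, self.sexes)
        st = edge_interaction_fstats(cohort)
        assert st.df1 == 1
        assert st.df2 == self.n - 6
        assert st.f[0, 1] == pytest.approx(self._oracle_f(), abs=1e-10)
        assert st.f[0, 1] == st.f[1, 0]

    def test_invariant_to_subject_order(self):
        cohort = _hand_cohort(self.y, self.scores, self.groups, self.ages, self.sexes)
        st = edge_interaction_fstats(cohort)
        perm = np.random.default_rng(3).permutation(self.n)
        cohort_p = _hand_cohort(
            self.y[perm],
            self.scores[perm],
            [self.groups[i] for i in perm],
            self.ages[perm],
            self.sexes[perm],
        )
        st_p = edge_interaction_fstats(cohort_p)
        assert st_p.f[0, 1] == pytest.approx(st.f[0, 1], abs=1e-10)

    def test_equal_slopes_yield_small_f(self):
        medians = []
        for seed in range(5):
            cfg = CohortConfig(
                n_case=11, n_control=16, n_nodes=30,
                slope_case=0.01, slope_control=0.01,
                planted_edges=planted_subnetwork(8, 10, 30, seed=1),
                seed=seed,
            )
            cohort, _ = generate_cohort(cfg)
            st = edge_interaction_fstats(cohort)
            medians.append(np.median(st.f_values))
        assert np.median(medians) < 1.0

    def test_constant_edge_flagged_zero(self):
        y = np.full(self.n, 0.4)
        cohort = _hand_cohort(y, self.scores, self.groups, self.ages, self.sexes)
        st = edge_interaction_fstats(cohort)
        assert st.f[0, 1] == 0.0


class TestComponents:
    def _map(self, edges, fvals, n=8):
        f = np.full((n, n), np.nan)
        mask = np.zeros((n, n), dtype=bool)
        idx = np.array(edges)
        for (i, j), v in zip(edges, fvals):
            f[i, j] = f[j, i] = v
            mask[i, j] = mask[j, i] = True
        return EdgeStatMap(f=f, mask=mask, df1=1, df2=10, edge_index=idx)

    def test_hand_union_find_case(self):
        st = self._map([(1, 2), (2, 3), (5, 6)], [9.0, 8.0, 7.5])
        comps = supra_threshold_components(st, 7.0)
        assert [c.size for c in comps] == [2, 1]
        assert comps[0].nodes == [1, 2, 3]
        assert comps[1].edges == [(5, 6)]

    def test_no_edge_survives(self):
        st = self._map([(1, 2), (2, 3)], [1.0, 2.0])
        assert supra_threshold_components(st, 7.0) == []

    def test_zero_threshold_returns_mask_components(self):
        st = self._map([(0, 1), (1, 2), (4, 5)], [0.1, 0.2, 0.3])
        comps = supra_threshold_components(st, 0.0)
        assert sorted(c.size for c in comps) == [1, 2]


@pytest.fixture(scope="module")
def planted_fit():
    planted = planted_subnetwork(seed=7)
    cfg = CohortConfig(
        planted_edges=planted, slope_case=0.010, slope_control=0.0,
        noise_sd=0.02, seed=11,
    )
    cohort, truth = generate_cohort(cfg)
    model = NBSInteraction(cohort)
    return model, truth, model.fit(n_permutations=200, seed=5)


class TestNBSInteraction:
    def test_planted_subnetwork_recovered(self, planted_fit):
        _, truth, res = planted_fit
        sig = res.significant
        assert sig, "expected a significant component"
        jac = jaccard_edges(sig[0].edges, truth.planted_edges)
        assert jac > 0.5

    def test_deterministic_under_seed(self, planted_fit):
        model, _, res = planted_fit
        res2 = model.fit(n_permutations=200, seed=5)
        assert [c.p for c in res2.components] == [c.p for c in res.components]
        assert np.array_equal(res2.null_max_sizes, res.null_max_sizes)

    def test_p_monotone_in_component_size(self, planted_fit):
        _, _, res = planted_fit
        sizes = [c.size for c in res.components]
        ps = [c.p for c in res.components]
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            assert s1 >= s2 and p1 <= p2

    def test_add_one_variant_strictly_positive(self, planted_fit):
        model, _, _ = planted_fit
        res = model.fit(n_permutations=100, seed=5, add_one=True)
        assert all(c.p >= 1 / 101 for c in res.components)

    def test_doubling_k_perturbs_p_within_monte_carlo_bound(self, planted_fit):
        model, _, _ = planted_fit
        p500 = model.fit(n_permutations=500, seed=21).components[0].p
        p1000 = model.fit(n_permutations=1000, seed=22).components[0].p
        assert abs(p500 - p1000) < 2 / np.sqrt(500)

    def test_summary_reports_threshold_and_components(self, planted_fit):
        _, _, res = planted_fit
        text = res.summary()
        assert "F(1,48)" in text
        assert "component 1" in text

    def test_bad_arguments_rejected(self, planted_fit):
        model, _, _ = planted_fit
        with pytest.raises(ValueError):
            model.fit(n_permutations=10)
        with pytest.raises(ValueError):
            model.fit(scheme="bogus")


def test_exhaustive_relabelling_matches_monte_carlo_null():
    """On an 8-subject toy, the Monte-Carlo null of the max component size
    matches exhaustive enumeration over all 70 group relabellings."""
    rng = np.random.default_rng(13)
    n, nodes = 8, 6
    w = np.zeros((n, nodes, nodes))
    iu = np.triu_indices(nodes, 1)
    for s in range(n):
        vals = rng.uniform(0.3, 0.6, len(iu[0]))
        w[s][iu] = vals
        w[s] = w[s] + w[s].T
    groups = ["case"] * 4 + ["control"] * 4
    scores = rng.normal(10, 3, n)
    ages = rng.uniform(6, 8, n)
    sexes = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    cohort = make_cohort(w, groups, scores=scores, ages=ages, sexes=sexes)

    threshold = 5.0
    from faconn.nbs import _components_from_edges, _design_matrices, _nested_f

    manifest = cohort.manifest
    full, red = _design_matrices(manifest, "mabc2_total", ("age", "sex"))
    stack = cohort.weight_stack()
    st = edge_interaction_fstats(cohort)
    y = stack[:, st.edge_index[:, 0], st.edge_index[:, 1]]

    def max_size(case_idx):
        g = np.zeros(n)
        g[list(case_idx)] = 1.0
        full_p = full.copy()
        full_p[:, 1] = g
        full_p[:, 3] = g * full[:, 2]
        red_p = red.copy()
        red_p[:, 1] = g
        qf, _ = np.linalg.qr(full_p)
        qr_, _ = np.linalg.qr(red_p)
        f = _nested_f(qf, qr_, y, n - 6)
        comps = _components_from_edges(st.edge_index, f >= threshold, nodes)
        return comps[0].size if comps else 0

    exhaustive = np.array(
        [max_size(c) for c in combinations(range(n), 4)], dtype=float
    )
    res = NBSInteraction(cohort).fit(
        n_permutations=2000, edge_f=threshold, seed=3, scheme="group_label"
    )
    mc = res.null_max_sizes
    hi = int(max(exhaustive.max(), mc.max()))
    p_ex = np.array([(exhaustive == s).mean() for s in range(hi + 1)])
    p_mc = np.array([(mc == s).mean() for s in range(hi + 1)])
    assert 0.5 * np.abs(p_ex - p_mc).sum() < 0.05  # total variation distance
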