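"""Network-based statistics: edge-wise tests, suprathreshold components
against hand/union-find oracles, and permutation FWER behaviour."""

import numpy as np
import pytest
from scipy import stats

import restdyn as rd
from restdyn.netstats import Component, _max_component_size, _triu


def _stack_from_edges(n_sub, n, edge_values):
    """Build subject stacks where given edges carry given per-subject values."""
    out = np.zeros((n_sub, n, n))
    for (i, j), vals in edge_values.items():
        out[:, i, j] = vals
        out[:, j, i] = vals
    return out


class TestEdgeStats:
    def test_identical_conditions_give_zero_or_missing(self, rng):
        A = rd.simulate_connectome_set(5, 6, seed=1, n_conditions=1)[0]
        t = rd.edge_paired_t(A, A)
        off = t[np.triu_indices(6, 1)]
        assert np.all(np.isnan(off))

    def test_closed_form_paired_t(self):
        # one edge with diffs (1, 2, 3): mean 2, SD 1, n 3 -> t = 2 sqrt(3)
        n = 4
        B = np.zeros((3, n, n))
        A = _stack_from_edges(3, n, {(0, 1): [1.0, 2.0, 3.0]})
        # give other edges noise so they are not zero-variance
        rng = np.random.default_rng(0)
        noise = rng.standard_normal((3, n, n)) * 0.1
        noise = (noise + np.swapaxes(noise, 1, 2)) / 2
        t = rd.edge_paired_t(A + noise, B + noise)
        assert t[0, 1] == pytest.approx(2 * np.sqrt(3))

    def test_sign_flip_antisymmetry(self, rng):
        mats = rd.simulate_connectome_set(8, 5, seed=2)
        t_ab = rd.edge_paired_t(mats[0], mats[1])
        t_ba = rd.edge_paired_t(mats[1], mats[0])
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(t_ab[iu], -t_ba[iu], atol=1e-10)

    def test_correlation_with_own_edge_is_one(self, rng):
        mats = rd.simulate_connectome_set(10, 5, seed=3, n_conditions=1)[0]
        cov = mats[:, 0, 1]
        r = rd.edge_correlation(mats, cov)
        assert r[0, 1] == pytest.approx(1.0)

    def test_covariate_negation_flips_r(self, rng):
        mats = rd.simulate_connectome_set(10, 5, seed=4, n_conditions=1)[0]
        cov = rng.standard_normal(10)
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(
            rd.edge_correlation(mats, cov)[iu], -rd.edge_correlation(mats, -cov)[iu],
            atol=1e-12,
        )

    def test_null_r_distribution_matches_permutation_null(self, rng):
        # independent covariate: observed edge r's should be exchangeable
        # with r's computed under covariate reshuffling (two-sample KS)
        mats = rd.simulate_connectome_set(30, 8, seed=5, n_conditions=1)[0]
        cov = rng.standard_normal(30)
        iu = np.triu_indices(8, 1)
        observed = rd.edge_correlation(mats, cov)[iu]
        perm_rs = np.concatenate(
            [rd.edge_correlation(mats, rng.permutation(cov))[iu] for _ in range(40)]
        )
        assert stats.ks_2samp(observed, perm_rs).pvalue > 0.01

    def test_constant_covariate_rejected(self, rng):
        mats = rd.simulate_connectome_set(6, 4, seed=6, n_conditions=1)[0]
        with pytest.raises(ValueError):
            rd.edge_correlation(mats, np.ones(6))


class TestComponents:
    @staticmethod
    def _matrix_with_edges(n, edges, value=5.0):
        m = np.zeros((n, n))
        for i, j in edges:
            m[i, j] = m[j, i] = value
        return m

    def test_threshold_above_max_gives_nothing(self, rng):
        m = rng.standard_normal((6, 6))
        m = (m + m.T) / 2
        assert rd.suprathreshold_components(m, np.abs(m).max() + 1, "greater") == []

    def test_hand_component_structure(self):
        m = self._matrix_with_edges(10, [(1, 2), (2, 3), (7, 8)])
        comps = rd.suprathreshold_components(m, 3.5, "greater")
        sizes = sorted(c.size for c in comps)
        assert sizes == [1, 2]
        big = max(comps, key=lambda c: c.size)
        assert big.nodes == [1, 2, 3]

    def test_cycle_counts_edges_not_nodes(self):
        m = self._matrix_with_edges(6, [(0, 1), (1, 2), (2, 3), (3, 0)])
        comps = rd.suprathreshold_components(m, 3.5, "greater")
        assert len(comps) == 1
        assert comps[0].size == 4 and len(comps[0].nodes) == 4

    def test_union_find_oracle_random_graphs(self, rng):
        # independent union-find implementation as oracle
        def uf_components(n, edges):
            parent = list(range(n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, j in edges:
                parent[find(i)] = find(j)
            groups = {}
            for i, j in edges:
                groups.setdefault(find(i), []).append((i, j))
            return sorted(len(v) for v in groups.values())

        for _ in range(20):
            n = 12
            m = rng.standard_normal((n, n))
            m = (m + m.T) / 2
            comps = rd.suprathreshold_components(m, 1.0, "greater")
            iu = _triu(n)
            edges = [
                (int(i), int(j))
                for i, j in zip(*iu)
                if m[i, j] > 1.0
            ]
            assert sorted(c.size for c in comps) == uf_components(n, edges)

    def test_negative_tail(self):
        m = self._matrix_with_edges(5, [(0, 1)], value=-5.0)
        assert rd.suprathreshold_components(m, 3.5, "greater") == []
        comps = rd.suprathreshold_components(m, 3.5, "less")
        assert len(comps) == 1 and comps[0].size == 1


class TestNbsFwer:
    @staticmethod
    def _paired_with_effect(n_sub=20, n=10, delta=0.3, seed=0):
        mats = rd.simulate_connectome_set(n_sub, n, seed=seed)
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)]
        post = rd.plant_connectome_effect(mats[1], edges, delta)
        return mats[0], post, edges

    def test_planted_component_detected(self):
        pre, post, edges = self._paired_with_effect(seed=42)
        res = rd.nbs_fwer((post, pre), "paired", n_perm=1000, seed=1)
        assert res.components, "no suprathreshold component found"
        best = res.components[0]
        assert best.p_fwer < 0.05
        assert len(set(best.edges) & set(edges)) >= 4

    def test_p_monotone_in_component_size(self):
        pre, post, _ = self._paired_with_effect(seed=7)
        res = rd.nbs_fwer((post, pre), "paired", n_perm=500, seed=2)
        sizes = [c.size for c in res.components]
        ps = [c.p_fwer for c in res.components]
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            assert s1 >= s2 and p1 <= p2

    def test_higher_threshold_never_grows_components(self, rng):
        m = rng.standard_normal((12, 12)) * 3
        m = (m + m.T) / 2
        lo = rd.suprathreshold_components(m, 2.0, "greater")
        hi = rd.suprathreshold_components(m, 4.0, "greater")
        assert sum(c.size for c in hi) <= sum(c.size for c in lo)
        assert max((c.size for c in hi), default=0) <= max((c.size for c in lo), default=0)

    def test_seeded_null_is_reproducible(self):
        pre, post, _ = self._paired_with_effect(seed=3)
        a = rd.nbs_fwer((post, pre), "paired", n_perm=300, seed=9)
        b = rd.nbs_fwer((post, pre), "paired", n_perm=300, seed=9)
        np.testing.assert_array_equal(a.null_max_size, b.null_max_size)
        assert [c.p_fwer for c in a.components] == [c.p_fwer for c in b.components]

    def test_subject_storage_order_irrelevant(self):
        pre, post, _ = self._paired_with_effect(seed=5)
        perm = np.random.default_rng(0).permutation(pre.shape[0])
        a = rd.nbs_fwer((post, pre), "paired", n_perm=200, seed=4)
        b = rd.nbs_fwer((post[perm], pre[perm]), "paired", n_perm=200, seed=4)
        assert sorted(c.size for c in a.components) == sorted(c.size for c in b.components)

    def test_correlation_design_finds_covariate_linked_component(self, rng):
        n_sub, n = 25, 8
        mats = rd.simulate_connectome_set(n_sub, n, seed=11, n_conditions=1)[0]
        cov = rng.standard_normal(n_sub)
        # plant a covariate-tracking component on a 3-edge path
        for (i, j) in [(0, 1), (1, 2), (2, 3)]:
            mats[:, i, j] += 0.2 * cov
            mats[:, j, i] = mats[:, i, j]
        res = rd.nbs_fwer(mats, "correlation", covariate=cov, n_perm=1000, seed=12)
        assert res.components and res.components[0].p_fwer < 0.05
        assert set(res.components[0].nodes) >= {0, 1, 2, 3}

    def test_node_weights_sum_incident_edges(self):
        pre, post, _ = self._paired_with_effect(seed=13)
        res = rd.nbs_fwer((post, pre), "paired", n_perm=100, seed=1)
        w = res.node_weights()
        for comp in res.components:
            for i, j in comp.edges:
                assert w[i] > 0 and w[j] > 0

    def test_max_component_size_shortcut_matches_full(self, rng):
        n = 10
        iu = _triu(n)
        for _ in range(30):
            keep = rng.random(iu[0].size) < 0.15
            full = rd.suprathreshold_components(_mask_matrix(keep, n), 0.5, "greater")
            expect = max((c.size for c in full), default=0)
            assert _max_component_size(keep, iu, n) == expect


def _mask_matrix(keep, n):
    m = np.zeros((n, n))
    iu = _triu(n)
    m[iu[0][keep], iu[1][keep]] = 1.0
    return m + m.T
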