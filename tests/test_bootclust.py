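"""Clustering with multiscale-bootstrap support: distances, UPGMA, AU fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dddkit.bootclust import (BootstrapConfig, Dendrogram, fit_au, hcluster,
                              multiscale_bootstrap, pick_clusters,
                              profile_distance, DendroNode, ClusterSupport,
                              ScaleCount, _support_from_counts)


def dist_frame(values, labels):
    return pd.DataFrame(np.asarray(values, dtype=float), index=labels,
                        columns=labels)


class TestProfileDistance:
    def test_identical_rows_have_zero_distance(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3], [0, 5, 1]],
                         index=list("abc"))
        d = profile_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_anticorrelated_rows_have_distance_two(self):
        m = pd.DataFrame([[1, 2, 3], [3, 2, 1], [0, 5, 1]],
                         index=list("abc"))
        d = profile_distance(m)
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.random((5, 4)), index=list("abcde"))
        d = profile_distance(m)
        X = m.to_numpy()
        for i in range(5):
            for j in range(5):
                xi, xj = X[i], X[j]
                cov = ((xi - xi.mean()) * (xj - xj.mean())).mean()
                r = cov / (xi.std() * xj.std())
                assert d.iloc[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_constant_profile_named_in_error(self):
        m = pd.DataFrame([[1, 1, 1], [0, 5, 1], [2, 0, 4]],
                         index=["flat", "b", "c"])
        with pytest.raises(ValueError, match="flat"):
            profile_distance(m)

    def test_pairwise_complete_with_missing_values(self):
        m = pd.DataFrame([[1, 2, 3, 4], [1, 2, 3, np.nan], [4, 0, 2, 1]],
                         index=list("abc"))
        d = profile_distance(m)
        assert d.loc["a", "b"] == pytest.approx(0.0)

    def test_too_few_shared_columns_rejected(self):
        m = pd.DataFrame([[1, 2, np.nan, np.nan], [np.nan, np.nan, 3, 4],
                          [1, 2, 3, 4]], index=list("abc"))
        with pytest.raises(ValueError, match="fewer"):
            profile_distance(m)


class TestHCluster:
    def test_three_point_upgma_hand_arithmetic(self):
        d = dist_frame([[0, 1, 4], [1, 0, 5], [4, 5, 0]], list("abc"))
        dendro = hcluster(d)
        nodes = dendro.internal_nodes()
        assert nodes[0].members == frozenset("ab")
        assert nodes[0].height == pytest.approx(1.0)
        assert nodes[1].members == frozenset("abc")
        assert nodes[1].height == pytest.approx(4.5)

    def test_two_points_merge_at_their_distance(self):
        d = dist_frame([[0, 3], [3, 0]], list("xy"))
        dendro = hcluster(d)
        assert dendro.root.height == pytest.approx(3.0)

    def test_ultrametric_input_reproduced_exactly(self):
        # tree ((a,b):1, (c,d):2):4
        d = dist_frame([[0, 1, 4, 4], [1, 0, 4, 4],
                        [4, 4, 0, 2], [4, 4, 2, 0]], list("abcd"))
        dendro = hcluster(d)
        by_members = {n.members: n.height for n in dendro.internal_nodes()}
        assert by_members == {
            frozenset("ab"): pytest.approx(1.0),
            frozenset("cd"): pytest.approx(2.0),
            frozenset("abcd"): pytest.approx(4.0)}

    def test_tie_break_is_lexicographic_and_deterministic(self):
        d = dist_frame([[0, 1, 1], [1, 0, 1], [1, 1, 0]], list("cab"))
        first = hcluster(d).internal_nodes()[0].members
        assert first == frozenset("ab")

    def test_matches_scipy_average_linkage_heights(self):
        from scipy.cluster.hierarchy import linkage
        rng = np.random.default_rng(6)
        X = rng.random((8, 5))
        d = profile_distance(pd.DataFrame(X, index=list("abcdefgh")))
        dendro = hcluster(d)
        from scipy.spatial.distance import squareform
        Z = linkage(squareform(d.values, checks=False), method="average")
        ours = sorted(n.height for n in dendro.internal_nodes())
        theirs = sorted(Z[:, 2])
        assert np.allclose(ours, theirs)


class TestAUFit:
    def test_noiseless_curve_recovers_coefficients(self):
        rho = np.round(np.arange(0.5, 1.45, 0.1), 1)
        v, c = 1.0, 0.5
        bp = 1 - norm.cdf(v * np.sqrt(rho) + c / np.sqrt(rho))
        au, bp_fit, v_est, c_est, chi2 = fit_au(bp, rho, 1000)
        assert v_est == pytest.approx(v, abs=1e-6)
        assert c_est == pytest.approx(c, abs=1e-6)
        assert au == pytest.approx(1 - norm.cdf(0.5), abs=1e-9)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_au_close_to_bp_when_c_is_zero(self):
        rho = np.round(np.arange(0.5, 1.45, 0.1), 1)
        bp = 1 - norm.cdf(0.8 * np.sqrt(rho))
        au, bp_fit, *_ = fit_au(bp, rho, 1000)
        assert au == pytest.approx(bp_fit, abs=1e-6)

    def test_single_scale_rejected(self):
        with pytest.raises(ValueError):
            fit_au([0.5], [1.0], 1000)

    def test_fully_stable_node_gets_au_one(self):
        counts = [ScaleCount(rho=r, n_boot=1000, hits=1000)
                  for r in (0.5, 1.0, 1.4)]
        sup = _support_from_counts(frozenset("ab"), counts)
        assert sup.au == 1.0 and sup.bp == 1.0

    def test_never_recovered_node_gets_au_zero(self):
        counts = [ScaleCount(rho=r, n_boot=1000, hits=0)
                  for r in (0.5, 1.0, 1.4)]
        sup = _support_from_counts(frozenset("ab"), counts)
        assert sup.au == 0.0


class TestMultiscaleBootstrap:
    @staticmethod
    def blocky_matrix(rng, n_per_block=4, n_cols=12):
        base = np.zeros((2 * n_per_block, n_cols))
        base[:n_per_block, :n_cols // 2] = 1.0
        base[n_per_block:, n_cols // 2:] = 1.0
        return pd.DataFrame(base + rng.normal(0, 0.05, base.shape),
                            index=[f"g{i}" for i in range(2 * n_per_block)])

    def test_root_always_hit_and_run_reproducible(self):
        rng = np.random.default_rng(1)
        mat = self.blocky_matrix(rng)
        config = BootstrapConfig(seed=5, n_boot=100, scales=(0.6, 1.0, 1.3))
        sup1, den1 = multiscale_bootstrap(mat, config)
        sup2, den2 = multiscale_bootstrap(mat, config)
        root1 = [s for s in sup1 if s.members == frozenset(mat.index)][0]
        assert all(c.hits == c.n_boot for c in root1.scales)
        assert root1.au == 1.0
        assert [(s.members, s.au, s.bp,
                 tuple(c.hits for c in s.scales)) for s in sup1] == \
               [(s.members, s.au, s.bp,
                 tuple(c.hits for c in s.scales)) for s in sup2]

    def test_stable_blocks_get_high_au(self):
        rng = np.random.default_rng(2)
        mat = self.blocky_matrix(rng)
        config = BootstrapConfig(seed=7, n_boot=200)
        supports, dendro = multiscale_bootstrap(mat, config)
        by_members = {s.members: s for s in supports}
        b1 = frozenset(f"g{i}" for i in range(4))
        b2 = frozenset(f"g{i}" for i in range(4, 8))
        assert by_members[b1].au > 0.95
        assert by_members[b2].au > 0.95

    def test_larger_nboot_reduces_au_spread(self):
        rng = np.random.default_rng(4)
        # weaker structure so AU is genuinely uncertain
        base = self.blocky_matrix(rng)
        mat = base + rng.normal(0, 0.45, base.shape)
        b1 = frozenset(f"g{i}" for i in range(4))

        def au_values(n_boot, seeds):
            out = []
            for seed in seeds:
                sup, _ = multiscale_bootstrap(
                    mat, BootstrapConfig(seed=seed, n_boot=n_boot,
                                         scales=(0.6, 0.8, 1.0, 1.2)))
                by = {s.members: s for s in sup}
                if b1 in by and by[b1].au is not None:
                    out.append(by[b1].au)
            return np.array(out)

        small = au_values(100, range(8))
        large = au_values(400, range(8))
        assert len(small) == len(large) == 8
        assert large.std() < small.std() + 0.02


class TestPickClusters:
    @staticmethod
    def make_supports(dendro, au_by_members):
        return [ClusterSupport(members=n.members, scales=[],
                               au=au_by_members.get(n.members), bp=None)
                for n in dendro.internal_nodes()]

    @staticmethod
    def four_leaf_tree():
        d = dist_frame([[0, 1, 4, 4], [1, 0, 4, 4],
                        [4, 4, 0, 2], [4, 4, 2, 0]], list("abcd"))
        return hcluster(d)

    def test_nothing_significant_returns_empty(self):
        dendro = self.four_leaf_tree()
        supports = self.make_supports(dendro, {})
        assert pick_clusters(supports, dendro) == []

    def test_two_significant_children_under_weak_root(self):
        dendro = self.four_leaf_tree()
        supports = self.make_supports(dendro, {
            frozenset("ab"): 0.99, frozenset("cd"): 0.97,
            frozenset("abcd"): 0.50})
        picked = pick_clusters(supports, dendro)
        assert set(picked) == {frozenset("ab"), frozenset("cd")}

    def test_significant_parent_prunes_children(self):
        d = dist_frame([[0, 1, 2, 9], [1, 0, 2, 9],
                        [2, 2, 0, 9], [9, 9, 9, 0]], list("abcd"))
        dendro = hcluster(d)
        supports = self.make_supports(dendro, {
            frozenset("ab"): 0.99, frozenset("abc"): 0.99})
        picked = pick_clusters(supports, dendro)
        assert picked == [frozenset("abc")]

    def test_root_never_reported(self):
        dendro = self.four_leaf_tree()
        supports = self.make_supports(dendro, {frozenset("abcd"): 1.0})
        assert pick_clusters(supports, dendro) == []

    def test_planted_two_groups_recovered(self):
        from dddkit.synthetic import two_group_similarity_matrix
        mat, groups = two_group_similarity_matrix(seed=5)
        supports, dendro = multiscale_bootstrap(
            mat, BootstrapConfig(seed=5, n_boot=200))
        picked = pick_clusters(supports, dendro, alpha=0.95)
        expected = {frozenset(g for g, k in groups.items() if k == 0),
                    frozenset(g for g, k in groups.items() if k == 1)}
        assert set(picked) == expected
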