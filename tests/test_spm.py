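"""Node-wise linear models, cluster formation and corrected inference."""

import numpy as np
import pytest
from scipy import stats

import femurmap as fm
from femurmap.errors import ArgumentError, DesignError
from femurmap.spm import (
    build_design,
    build_mask,
    cluster_inference,
    composite_map,
    fit_node_models,
    percent_difference_summary,
    supra_threshold_clusters,
)
from femurmap.synth import make_field_cohort


@pytest.fixture(scope="module")
def template(stats_template):
    outer, truth = stats_template
    return outer, truth, outer.edges


class TestNodeModels:
    def test_noiseless_beta_recovered(self):
        rng = np.random.default_rng(0)
        S, N = 15, 40
        X = np.column_stack(
            [np.ones(S), rng.integers(0, 2, S), rng.normal(size=S)]
        )
        beta = rng.normal(size=(3, N))
        Y = X @ beta
        from femurmap.spm import DesignMatrix

        design = DesignMatrix(X=X, columns=["i", "g", "w"],
                              contrast=np.array([0.0, 1.0, 0.0]))
        pinv = np.linalg.pinv(X)
        assert np.abs(pinv @ Y - beta).max() < 1e-9
        t, df = fit_node_models(Y + rng.normal(size=(S, N)) * 1e-12, design)
        assert df == S - 3

    def test_two_group_t_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(3, 0.3, (24, 60))
        g = np.array(["c"] * 12 + ["e"] * 12)
        design = build_design(g, "e", "c")
        t, df = fit_node_models(Y, design)
        oracle = stats.ttest_ind(Y[12:], Y[:12]).statistic
        assert np.abs(t - oracle).max() < 1e-9
        assert df == 22

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 30))
        g = np.array(["c"] * 10 + ["e"] * 10)
        w = rng.normal(size=20)
        perm = rng.permutation(20)
        d1 = build_design(g, "e", "c", {"w": w})
        d2 = build_design(g[perm], "e", "c", {"w": w[perm]})
        t1, _ = fit_node_models(Y, d1)
        t2, _ = fit_node_models(Y[perm], d2)
        np.testing.assert_allclose(t1, t2, atol=1e-9)

    def test_orthogonal_confound_leaves_contrast_unchanged(self):
        # a confound orthogonal to the design and the data changes nothing
        # but the residual df: the contrast estimate is identical and the
        # t-map matches exactly after the df renormalisation of sigma-hat
        rng = np.random.default_rng(3)
        S = 30
        g = np.array(["c"] * 15 + ["e"] * 15)
        Y = rng.normal(size=(S, 25))
        d1 = build_design(g, "e", "c")
        conf = rng.normal(size=S)
        Q, _ = np.linalg.qr(np.column_stack([d1.X, Y]))
        conf_orth = conf - Q @ (Q.T @ conf)
        d2 = build_design(g, "e", "c", {"conf": conf_orth})
        t1, df1 = fit_node_models(Y, d1)
        t2, df2 = fit_node_models(Y, d2)
        np.testing.assert_allclose(t1, t2 * np.sqrt(df1 / df2), atol=1e-9)
        b1 = np.linalg.pinv(d1.X) @ Y
        b2 = np.linalg.pinv(d2.X) @ Y
        np.testing.assert_allclose(d1.contrast @ b1, d2.contrast @ b2,
                                   atol=1e-9)

    def test_rank_deficiency_names_columns(self):
        g = np.array(["c"] * 5 + ["e"] * 5)
        with pytest.raises(DesignError, match="dup"):
            build_design(g, "e", "c", {"dup": (g == "e").astype(float)})


class TestMask:
    def test_all_thick_passes(self):
        th = np.full((6, 20), 3.0)
        assert build_mask(th, np.arange(3), 1.0).all()

    def test_planted_thin_patch_excluded(self):
        th = np.full((6, 20), 3.0)
        th[:3, 5:8] = 0.4  # control cohort thin patch
        m = build_mask(th, np.arange(3), 1.0)
        assert not m[5:8].any() and m[:5].all() and m[8:].all()

    def test_zero_threshold_excludes_nothing(self):
        th = np.abs(np.random.default_rng(0).normal(size=(4, 10)))
        assert build_mask(th, None, 0.0).all()


class TestClusters:
    def test_zero_t_map_gives_no_clusters(self, template):
        outer, _, edges = template
        t = np.zeros(outer.n_vertices)
        cl = supra_threshold_clusters(t, 20, np.ones(outer.n_vertices, bool),
                                      edges)
        assert cl == []

    def test_one_and_two_planted_patches(self, template):
        outer, truth, edges = template
        m1 = fm.synth._region_mask(truth.depth, truth.theta, 40, 55, 0.9, 2.2)
        m2 = fm.synth._region_mask(truth.depth, truth.theta, 85, 100, 3.5, 4.8)
        t = np.zeros(outer.n_vertices)
        for m in (m1,):
            t[m] = 10.0
        cl = supra_threshold_clusters(t, 20, np.ones_like(t, bool), edges)
        assert len(cl) == 1 and set(cl[0].nodes) == set(np.flatnonzero(m1))
        t[m2] = 10.0
        cl = supra_threshold_clusters(t, 20, np.ones_like(t, bool), edges)
        assert len(cl) == 2


class TestInference:
    def test_same_seed_bit_identical(self, template):
        outer, truth, edges = template
        mask = np.ones(outer.n_vertices, bool)
        feats, table = make_field_cohort(outer, 10, 10, None, 0.0, 0.1,
                                         np.random.default_rng(4))
        design = build_design(table.group.values, "loaded", "control")
        r1 = cluster_inference(feats, design, mask, edges, n_perm=200, seed=9)
        r2 = cluster_inference(feats, design, mask, edges, n_perm=200, seed=9)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]
        np.testing.assert_array_equal(r1.null_max_extent, r2.null_max_extent)

    def test_seed_required_for_permutation(self, template):
        outer, _, edges = template
        feats = np.random.default_rng(0).normal(3, 0.2, (8, outer.n_vertices))
        design = build_design(np.array(["c"] * 4 + ["e"] * 4), "e", "c")
        with pytest.raises(ArgumentError):
            cluster_inference(feats, design, np.ones(outer.n_vertices, bool),
                              edges, seed=None)

    def test_planted_effect_found_with_dice(self, template):
        outer, truth, edges = template
        region = fm.synth._region_mask(truth.depth, truth.theta, 40, 60, 0.8, 2.4)
        feats, table = make_field_cohort(outer, 20, 20, region, 30.0, 0.10,
                                         np.random.default_rng(11))
        design = build_design(table.group.values, "loaded", "control")
        res = cluster_inference(feats, design, np.ones(outer.n_vertices, bool),
                                edges, n_perm=300, seed=1)
        sig = [c for c in res.clusters if c.significant]
        assert sig
        inter = np.intersect1d(sig[0].nodes, np.flatnonzero(region))
        dice = 2 * len(inter) / (len(sig[0].nodes) + region.sum())
        assert dice >= 0.5

    def test_rft_route_runs_and_orders_like_extent(self, template):
        outer, truth, edges = template
        region = fm.synth._region_mask(truth.depth, truth.theta, 40, 60, 0.8, 2.4)
        feats, table = make_field_cohort(outer, 15, 15, region, 40.0, 0.10,
                                         np.random.default_rng(12))
        design = build_design(table.group.values, "loaded", "control")
        with pytest.warns(UserWarning):
            res = cluster_inference(feats, design,
                                    np.ones(outer.n_vertices, bool), edges,
                                    method="rft", seed=0)
        ps = [c.p_value for c in res.clusters]
        exts = [c.extent for c in res.clusters]
        # larger clusters get smaller p
        order = np.argsort(exts)[::-1]
        assert all(ps[order[i]] <= ps[order[i + 1]] + 1e-12
                   for i in range(len(order) - 1))


class TestPercentDifference:
    def test_uniform_ratio_and_zero_difference(self, template):
        outer, _, edges = template
        rng = np.random.default_rng(5)
        ctrl = rng.uniform(2, 4, (10, outer.n_vertices))
        feats = np.vstack([ctrl, 1.3 * ctrl])
        from femurmap.spm import SpmResult, Cluster

        cl = Cluster(nodes=np.arange(50), extent=50, p_value=0.01,
                     direction="greater", peak_t=5.0, significant=True)
        res = SpmResult(tmap=np.zeros(outer.n_vertices), df=1,
                        mask=np.ones(outer.n_vertices, bool), clusters=[cl],
                        method="permutation", cluster_forming_p=0.005,
                        cluster_alpha=0.05, direction="greater")
        res = percent_difference_summary(res, feats, np.arange(10, 20),
                                         np.arange(10))
        assert cl.mean_percent_diff == pytest.approx(30.0, abs=1e-9)
        res2 = percent_difference_summary(res, np.vstack([ctrl, ctrl]),
                                          np.arange(10, 20), np.arange(10))
        assert cl.mean_percent_diff == pytest.approx(0.0, abs=1e-9)

    def test_invariant_to_common_rescaling(self, template):
        outer, truth, edges = template
        region = fm.synth._region_mask(truth.depth, truth.theta, 40, 60, 0.8, 2.4)
        feats, table = make_field_cohort(outer, 8, 8, region, 25.0, 0.05,
                                         np.random.default_rng(6))
        from femurmap.spm import Cluster, SpmResult

        cl = Cluster(nodes=np.flatnonzero(region), extent=int(region.sum()),
                     p_value=0.01, direction="greater", peak_t=5.0,
                     significant=True)

        def summary(F):
            res = SpmResult(tmap=np.zeros(outer.n_vertices), df=1,
                            mask=np.ones(outer.n_vertices, bool),
                            clusters=[cl], method="permutation",
                            cluster_forming_p=0.005, cluster_alpha=0.05,
                            direction="greater")
            percent_difference_summary(res, F, np.arange(8, 16), np.arange(8))
            return cl.mean_percent_diff

        a = summary(feats)
        b = summary(feats * 17.3)
        assert a == pytest.approx(b, abs=1e-9)

    def test_planted_40_percent_patch_recovered(self, template):
        outer, truth, edges = template
        region = fm.synth._region_mask(truth.depth, truth.theta, 40, 60, 0.8, 2.4)
        feats, table = make_field_cohort(outer, 20, 20, region, 40.0, 0.10,
                                         np.random.default_rng(7))
        design = build_design(table.group.values, "loaded", "control")
        res = cluster_inference(feats, design, np.ones(outer.n_vertices, bool),
                                edges, n_perm=300, seed=2)
        res = percent_difference_summary(res, feats, np.arange(20, 40),
                                         np.arange(20))
        sig = [c for c in res.clusters if c.significant]
        assert sig and 35.0 <= sig[0].mean_percent_diff <= 45.0


class TestCompositeMap:
    def _result(self, n, nodes, label, significant=True):
        from femurmap.spm import Cluster, SpmResult

        cl = Cluster(nodes=np.asarray(nodes), extent=len(nodes), p_value=0.01,
                     direction="greater", peak_t=4.0, significant=significant)
        return SpmResult(tmap=np.zeros(n), df=10, mask=np.ones(n, bool),
                         clusters=[cl], method="permutation",
                         cluster_forming_p=0.005, cluster_alpha=0.05,
                         direction="greater", label=label)

    def test_single_group_everywhere(self):
        n = 30
        labels, names = composite_map([self._result(n, np.arange(n), "HI")])
        assert all(s == frozenset({"HI"}) for s in labels)

    def test_overlap_labelled_with_pair(self):
        n = 30
        r1 = self._result(n, np.arange(0, 20), "HI")
        r2 = self._result(n, np.arange(10, 30), "OI")
        labels, _ = composite_map([r1, r2])
        assert labels[15] == frozenset({"HI", "OI"})
        assert labels[5] == frozenset({"HI"})
        assert labels[25] == frozenset({"OI"})

    def test_no_significance_gives_all_ns(self):
        n = 10
        labels, _ = composite_map(
            [self._result(n, np.arange(5), "HI", significant=False)]
        )
        assert all(s == frozenset() for s in labels)

    def test_mismatched_templates_rejected(self):
        with pytest.raises(ArgumentError):
            composite_map([self._result(10, [0], "a"), self._result(12, [0], "b")])
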