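"""Normalization, proliferation classification, module scoring, pseudocells."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import sctrait as st


def _adata(counts, genes=None, obs=None):
    counts = np.asarray(counts, dtype=np.float64)
    n_cells, n_genes = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    adata = ad.AnnData(
        X=counts,
        obs=obs if obs is not None else pd.DataFrame(index=[f"c{i}" for i in range(n_cells)]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    return adata


def _normalized(counts, **kw):
    return st.normalize(_adata(counts, **kw))


class TestNormalize:
    def test_identical_cells_stay_identical(self):
        out = _normalized([[1, 2, 3], [1, 2, 3], [4, 0, 0]])
        assert np.allclose(out.X[0], out.X[1])

    def test_equal_depths_scale_by_one(self):
        counts = np.array([[1, 2, 3], [3, 2, 1]])
        out = _normalized(counts)
        assert np.allclose(out.X, np.log1p(counts))

    def test_doubled_cell_collapses_to_same_profile(self):
        # doubling a cell's counts only changes its depth factor
        counts = np.array([[1.0, 2, 3], [2, 4, 6], [6, 6, 6]])
        out = _normalized(counts)
        assert np.allclose(out.X[0], out.X[1])

    def test_zero_count_cells_dropped_and_logged(self):
        out = _normalized([[1, 2, 3], [0, 0, 0]])
        assert out.n_obs == 1
        assert out.uns["normalization"]["n_cells_dropped"] == 1

    def test_counts_preserved_in_layer(self):
        counts = np.array([[1.0, 2, 3], [4, 5, 6]])
        out = _normalized(counts)
        assert np.allclose(np.asarray(out.layers["counts"]), counts)


class TestCycleScore:
    def test_mean_over_panel_genes(self):
        adata = _normalized([[1, 1, 1]])
        adata.X = np.array([[3.0, 5.0, 100.0]])
        s = st.cycle_score(adata, st.GenePanel("cc", ["g0", "g1"]))
        assert s.iloc[0] == pytest.approx(4.0)

    def test_missing_panel_genes_excluded_from_denominator(self):
        adata = _normalized([[1, 1]])
        adata.X = np.array([[3.0, 5.0]])
        s = st.cycle_score(adata, st.GenePanel("cc", ["g0", "g1", "absent"]))
        assert s.iloc[0] == pytest.approx(4.0)

    def test_all_zero_cell_scores_zero(self):
        adata = _normalized([[0, 0, 1], [2, 2, 2]])
        assert st.cycle_score(adata, st.GenePanel("cc", ["g0", "g1"])).iloc[0] == 0.0

    def test_entirely_absent_panel_is_an_error(self):
        adata = _normalized([[1, 2]])
        with pytest.raises(ValueError, match="ghost"):
            st.cycle_score(adata, st.GenePanel("ghost", ["nope"]))

    def test_requires_normalization(self):
        adata = _adata([[1, 2]])
        with pytest.raises(ValueError, match="normalize"):
            st.cycle_score(adata, st.GenePanel("cc", ["g0"]))

    def test_total_statistic_option(self):
        adata = _normalized([[1, 1]])
        adata.X = np.array([[3.0, 5.0]])
        s = st.cycle_score(adata, st.GenePanel("cc", ["g0", "g1"]), statistic="total")
        assert s.iloc[0] == pytest.approx(8.0)


class TestClassifyProliferating:
    def test_threshold_is_mean_of_cluster_means(self):
        scores = pd.Series([2.0, 2.0, 6.0, 5.0, 4.0], index=list("abcde"))
        clusters = pd.Series(["x", "x", "y", "y", "y"], index=list("abcde"))
        flags, tau = st.classify_proliferating(scores, clusters)
        assert tau == pytest.approx((2.0 + 5.0) / 2)  # unweighted over clusters
        assert flags.tolist() == [False, False, True, True, True]

    def test_strictness_at_the_threshold(self):
        scores = pd.Series([2.0, 6.0, 4.0, 5.0], index=list("abcd"))
        clusters = pd.Series(["x", "y", "x", "y"], index=list("abcd"))
        # cluster means 3 and 5.5 -> tau 4.25: 5 is above, 4 is not
        flags, tau = st.classify_proliferating(scores, clusters)
        assert tau == pytest.approx(4.25)
        assert flags.tolist() == [False, True, False, True]

    def test_all_equal_scores_flag_nothing(self):
        scores = pd.Series([3.0, 3.0, 3.0], index=list("abc"))
        clusters = pd.Series(["x", "x", "y"], index=list("abc"))
        flags, tau = st.classify_proliferating(scores, clusters)
        assert tau == 3.0 and not flags.any()

    def test_grand_mean_flavor(self):
        scores = pd.Series([0.0, 0.0, 0.0, 4.0], index=list("abcd"))
        clusters = pd.Series(["x", "x", "x", "y"], index=list("abcd"))
        _, tau_cluster = st.classify_proliferating(scores, clusters)
        _, tau_grand = st.classify_proliferating(scores, clusters, threshold="grand_mean")
        assert (tau_cluster, tau_grand) == (2.0, 1.0)

    def test_invariant_to_cell_order(self, sc_norm):
        scores = st.cycle_score(sc_norm, st.GenePanel("cc", [f"g{i:04d}" for i in range(98)]))
        clusters = sc_norm.obs["cluster"]
        f1, _ = st.classify_proliferating(scores, clusters)
        perm = np.random.default_rng(0).permutation(len(scores))
        f2, _ = st.classify_proliferating(scores.iloc[perm], clusters.iloc[perm])
        assert f1.sort_index().equals(f2.sort_index())


class TestCycleIndex:
    def test_simple_fraction(self):
        flags = pd.Series([True] * 3 + [False] * 7)
        groups = pd.Series(["g"] * 10)
        assert st.cycle_index(flags, groups)["g"] == pytest.approx(0.30)

    def test_no_flags_means_all_zero(self):
        flags = pd.Series([False] * 6)
        groups = pd.Series(["a", "a", "b", "b", "c", "c"])
        assert (st.cycle_index(flags, groups) == 0).all()

    def test_cross_grouping_and_count_additivity(self, sc_norm):
        panel = st.GenePanel("cc", [f"g{i:04d}" for i in range(98)])
        flags, _ = st.classify_proliferating(
            st.cycle_score(sc_norm, panel), sc_norm.obs["cluster"]
        )
        idx = st.cycle_index(flags, sc_norm.obs[["cluster", "timepoint"]])
        assert ((idx >= 0) & (idx <= 1)).all()
        counts = flags.groupby(
            [sc_norm.obs["cluster"], sc_norm.obs["timepoint"]], observed=True
        ).sum()
        assert counts.sum() == flags.sum()


class TestModuleScore:
    def test_two_group_z_score(self):
        obs = pd.DataFrame({"tp": ["a", "a", "b", "b"]}, index=[f"c{i}" for i in range(4)])
        adata = _normalized(np.ones((4, 1)), obs=obs)
        adata.X = np.array([[2.0], [2.0], [4.0], [4.0]])
        ms = st.module_score(adata, [st.GenePanel("m", ["g0"])], group_key="tp")
        assert ms.loc["m"].tolist() == pytest.approx([-1.0, 1.0])

    def test_constant_gene_contributes_zero(self):
        obs = pd.DataFrame({"tp": ["a", "b"]}, index=["c0", "c1"])
        adata = _normalized(np.ones((2, 2)), obs=obs)
        adata.X = np.array([[2.0, 7.0], [4.0, 7.0]])  # g1 constant across groups
        ms = st.module_score(adata, [st.GenePanel("m", ["g0", "g1"])], group_key="tp")
        assert ms.loc["m"].tolist() == pytest.approx([-0.5, 0.5])

    def test_rows_have_zero_mean_and_bounded_sd(self, sc_norm):
        _, modules = st.default_panels(300)
        ms = st.module_score(sc_norm, modules, group_key="timepoint")
        assert np.allclose(ms.mean(axis=1), 0.0, atol=1e-12)
        assert (ms.std(axis=1, ddof=0) <= 1.0 + 1e-12).all()

    def test_group_order_follows_categorical(self, sc_norm):
        ms = st.module_score(
            sc_norm, [st.GenePanel("m", ["g0098"])], group_key="timepoint"
        )
        assert list(ms.columns) == ["Control", "LPS_2h", "LPS_4h", "LPS_8h"]


class TestClassifyTrajectory:
    @pytest.mark.parametrize(
        "scores,label",
        [
            ([-1.0, 0.8, 1.0, -0.9], "peaked"),
            ([-1.2, 0.3, 0.9, 0.7], "sustained"),
            ([0.01, -0.02, 0.0, 0.01], "flat"),
            ([1.0, 0.5, 0.0, -1.0], "flat"),  # monotone decrease is not a response
            ([-1.0, -0.5, 0.0, 1.0], "sustained"),  # max at the final point
        ],
    )
    def test_rule(self, scores, label):
        assert st.classify_trajectory(scores) == label

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            st.classify_trajectory([0.0, 1.0])


class TestPseudocell:
    def test_whole_cluster_draw_equals_cluster_mean(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(100, 20)).astype(float)
        obs = pd.DataFrame({"cluster": ["k"] * 100},
                           index=[f"c{i}" for i in range(100)])
        adata = _normalized(counts, obs=obs)
        pcs = st.pseudocell_aggregate(adata, size=100, n_pseudocells=3, seed=1)
        for row in np.asarray(pcs.X):
            assert row == pytest.approx(np.asarray(adata.X).mean(axis=0))

    def test_seeded_determinism(self, sc_norm):
        a = st.pseudocell_aggregate(sc_norm, size=50, n_pseudocells=4, seed=9)
        b = st.pseudocell_aggregate(sc_norm, size=50, n_pseudocells=4, seed=9)
        assert np.allclose(a.X, b.X)

    def test_small_cluster_skipped_with_warning(self, caplog):
        import logging

        rng = np.random.default_rng(1)
        obs = pd.DataFrame({"cluster": ["big"] * 50 + ["tiny"] * 10},
                           index=[f"c{i}" for i in range(60)])
        adata = _normalized(rng.poisson(3, size=(60, 8)) + 1, obs=obs)
        with caplog.at_level(logging.WARNING, logger="sctrait.cellstate"):
            pcs = st.pseudocell_aggregate(adata, size=20, n_pseudocells=2, seed=0)
        assert "skipping cluster" in caplog.text
        assert set(pcs.obs["cluster"]) == {"big"}

    def test_grand_mean_converges_to_cluster_mean(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(4, size=(1000, 15)).astype(float) + 1
        obs = pd.DataFrame({"cluster": ["k"] * 1000},
                           index=[f"c{i}" for i in range(1000)])
        adata = _normalized(counts, obs=obs)
        pcs = st.pseudocell_aggregate(adata, size=100, n_pseudocells=500, seed=3)
        grand = np.asarray(pcs.X).mean(axis=0)
        truth = np.asarray(adata.X).mean(axis=0)
        assert np.all(np.abs(grand - truth) / truth < 0.01)

    def test_invalid_size_rejected(self, sc_norm):
        with pytest.raises(ValueError):
            st.pseudocell_aggregate(sc_norm, size=0)
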