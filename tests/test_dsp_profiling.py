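"""DSP QC, normalization, differential expression, clustering, PCA, GSEA."""

import numpy as np
import pandas as pd
import pytest

import p16foci as p
from p16foci import dsp_profiling as d
from p16foci.errors import DataError


def make_experiment(counts: np.ndarray, hk=None, classes=None) -> p.DSPExperiment:
    genes = [f"g{i}" for i in range(counts.shape[0])]
    rois = [f"r{j}" for j in range(counts.shape[1])]
    classes = classes or ["focus"] * (counts.shape[1] // 2) + ["normal"] * (
        counts.shape[1] - counts.shape[1] // 2
    )
    return p.DSPExperiment(
        counts=pd.DataFrame(counts, index=genes, columns=rois),
        roi_meta=pd.DataFrame(
            {"roi_id": rois, "class": classes, "case_id": ["c1"] * len(rois)}
        ),
        housekeeping=[genes[i] for i in (hk or [])],
    )


def bh_adjust(pvals):
    """Independent Benjamini–Hochberg step-up with monotone flooring."""
    pvals = np.asarray(pvals, float)
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, pvals[idx] * m / rank)
        adj[idx] = running_min
    return adj


class TestQCFilter:
    def test_zero_total_roi_dropped(self):
        counts = np.ones((5, 4)) * 10
        counts[:, 2] = 0
        exp = make_experiment(counts, classes=["focus", "focus", "normal", "normal"])
        out = p.qc_filter(exp, min_roi_total=1)
        assert "r2" not in out.rois and len(out.rois) == 3

    def test_zero_thresholds_are_identity(self, dsp_experiment):
        exp, _ = dsp_experiment
        out = p.qc_filter(exp, min_roi_total=0, min_gene_mean=0)
        assert out.counts.shape == exp.counts.shape

    def test_planted_low_depth_roi_is_the_one_dropped(self):
        depth = [1.0] * 24
        depth[5] = 0.01  # 1% of the median depth
        exp, _ = p.gen_dsp(p.DSPSimSpec(seed=3, depth_factors=depth))
        median_total = float(exp.counts.sum(axis=0).median())
        out = p.qc_filter(exp, min_roi_total=0.1 * median_total)
        dropped = set(exp.rois) - set(out.rois)
        assert dropped == {exp.rois[5]}

    def test_housekeeping_never_dropped(self):
        counts = np.ones((4, 4)) * 100
        counts[0, :] = 0.01  # silent housekeeping gene
        exp = make_experiment(counts, hk=[0], classes=["focus", "focus", "normal", "normal"])
        out = p.qc_filter(exp, min_roi_total=0, min_gene_mean=1.0)
        assert "g0" in out.genes

    def test_class_wipeout_is_qc_failure(self):
        counts = np.ones((5, 4)) * 10
        counts[:, :2] = 0  # both focus ROIs under-sequenced
        exp = make_experiment(counts, classes=["focus", "focus", "normal", "normal"])
        with pytest.raises(DataError, match="focus"):
            p.qc_filter(exp, min_roi_total=1)


class TestNormalization:
    def test_identical_rois_are_fixed_points(self):
        counts = np.tile([[4.0], [16.0], [25.0]], (1, 5))
        exp = make_experiment(counts, hk=[0, 1], classes=["focus"] * 2 + ["normal"] * 3)
        assert np.allclose(p.hk_normalize(exp).to_numpy(), counts)
        assert np.allclose(p.q3_normalize(exp).to_numpy(), counts)

    def test_hk_factor_scales_out_doubled_roi(self):
        counts = np.tile([[4.0], [16.0], [25.0]], (1, 3))
        counts[:, 1] *= 2.0  # whole ROI doubled, incl. housekeeping
        exp = make_experiment(counts, hk=[0, 1], classes=["focus", "focus", "normal"])
        norm = p.hk_normalize(exp).to_numpy()
        # geomeans {8, 16, 8}: study geomean ~10.08, but ROI ratios are what matter
        assert np.allclose(norm[:, 0], norm[:, 1])
        assert np.allclose(norm[:, 0], norm[:, 2])

    def test_hk_hand_example_geomeans_2_4_8(self):
        # HK geomeans per ROI {2, 4, 8}; study geomean = 4 → factors {0.5, 1, 2}
        counts = np.array([[1.0, 2.0, 4.0], [4.0, 8.0, 16.0], [10.0, 10.0, 10.0]])
        exp = make_experiment(counts, hk=[0, 1], classes=["focus", "focus", "normal"])
        norm = p.hk_normalize(exp)
        assert np.allclose(norm.to_numpy()[2], [10.0 / 0.5, 10.0 / 1.0, 10.0 / 2.0])

    def test_zero_housekeeping_count_names_roi_and_gene(self):
        counts = np.array([[1.0, 0.0], [2.0, 2.0]])
        exp = make_experiment(counts, hk=[0], classes=["focus", "normal"])
        with pytest.raises(DataError, match="g0.*r1"):
            p.hk_normalize(exp)

    def test_q3_linear_interpolation(self):
        # Q3 of {1,2,3,4,100} is 4 under linear interpolation
        counts = np.array([[1.0], [2.0], [3.0], [4.0], [100.0]])
        col = pd.DataFrame(counts, columns=["r0"])
        assert float(col.quantile(0.75).iloc[0]) == 4.0  # transform input sanity
        exp = make_experiment(
            np.hstack([counts, counts * 2]), classes=["focus", "normal"]
        )
        norm = p.q3_normalize(exp)
        # factors are Q3 / geomean(Q3s) = {4, 8}/sqrt(32); ROI ratio scales out
        assert np.allclose(norm["r0"], norm["r1"])

    def test_scaled_roi_normalises_to_equal_matrices(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(3, 1, size=(50, 1))
        counts = np.hstack([base, base, base * 3.0])
        exp = make_experiment(counts, classes=["focus", "focus", "normal"])
        norm = p.q3_normalize(exp).to_numpy()
        assert np.allclose(norm[:, 0], norm[:, 2])

    @pytest.mark.parametrize("method", ["hk", "q3"])
    def test_idempotent_and_global_scale_invariant(self, dsp_experiment, method):
        exp, _ = dsp_experiment
        f = p.hk_normalize if method == "hk" else p.q3_normalize
        norm = f(exp)
        renorm = f(
            p.DSPExperiment(
                counts=norm, roi_meta=exp.roi_meta.copy(), housekeeping=exp.housekeeping
            )
        )
        assert np.abs(renorm.to_numpy() - norm.to_numpy()).max() < 1e-10
        scaled = f(
            p.DSPExperiment(
                counts=exp.counts * 7.5,
                roi_meta=exp.roi_meta.copy(),
                housekeeping=exp.housekeeping,
            )
        )
        assert np.allclose(scaled.to_numpy(), 7.5 * norm.to_numpy())


class TestDifferentialExpression:
    def test_identical_classes_select_nothing(self):
        rng = np.random.default_rng(0)
        block = rng.poisson(50, size=(100, 4)).astype(float)
        counts = np.hstack([block, block])
        norm = pd.DataFrame(counts, index=[f"g{i}" for i in range(100)],
                            columns=[f"r{j}" for j in range(8)])
        table = p.de_test(norm, [f"r{j}" for j in range(4)], [f"r{j}" for j in range(4, 8)])
        assert np.allclose(table["log2_fold_change"], 0.0)
        assert not table["selected"].any()

    def test_q_values_match_independent_bh(self, dsp_experiment):
        exp, _ = dsp_experiment
        norm = p.hk_normalize(exp)
        table = p.de_focus_vs_rest(exp, norm)
        assert np.allclose(table["q_value"], bh_adjust(table["p_value"]), atol=1e-12)
        # monotone: sorting by p and by q induces the same order
        by_p = table.sort_values("p_value", kind="stable").index
        assert (table.loc[by_p, "q_value"].diff().dropna() >= -1e-15).all()
        assert (table["q_value"] >= table["p_value"] - 1e-15).all()

    def test_planted_signature_recovered(self, dsp_experiment):
        """12 focus vs 12 pooled other ROIs, 97 planted genes at log2FC 2:
        the q<0.05 & FC>=1.5 rule recovers the signature with sensitivity
        >= 0.9 and empirical FDR <= 0.1."""
        exp, truth = dsp_experiment
        table = p.de_focus_vs_rest(exp, p.hk_normalize(exp))
        planted = set(truth["planted_genes"])
        selected = set(table.index[table["selected"]])
        tp = len(selected & planted)
        assert tp / len(planted) >= 0.9
        assert (len(selected) - tp) / max(len(selected), 1) <= 0.1
        # planted genes are up-regulated in foci
        assert (table.loc[sorted(planted), "log2_fold_change"] > 0).mean() > 0.95

    def test_zero_variance_conventions(self):
        counts = np.array(
            [[5.0, 5.0, 5.0, 5.0], [1.0, 1.0, 7.0, 7.0], [3.0, 4.0, 3.0, 5.0]]
        )
        norm = pd.DataFrame(counts, index=["flat", "step", "noisy"],
                            columns=["a1", "a2", "b1", "b2"])
        table = p.de_test(norm, ["a1", "a2"], ["b1", "b2"])
        assert table.loc["flat", "p_value"] == 1.0  # equal means, no variance
        assert table.loc["step", "p_value"] == 0.0  # separated, no variance

    def test_too_few_rois_rejected(self):
        norm = pd.DataFrame(np.ones((3, 3)), columns=["a", "b", "c"])
        with pytest.raises(DataError):
            p.de_test(norm, ["a"], ["b", "c"])

    def test_mannwhitney_flag(self, dsp_experiment):
        exp, truth = dsp_experiment
        norm = p.hk_normalize(exp)
        table = p.de_focus_vs_rest(exp, norm, method="mannwhitney")
        planted = set(truth["planted_genes"])
        selected = set(table.index[table["selected"]])
        assert len(selected & planted) / len(planted) >= 0.9


class TestClustering:
    def test_identical_profiles_merge_first_at_zero(self):
        X = np.array([[1.0, 2.0, 2.0, 9.0], [1.0, 2.0, 2.0, 9.0], [9.0, 1.0, 1.0, 1.0]]).T
        m = pd.DataFrame(X, columns=["a", "b", "c"])
        res = p.hier_cluster(m, axis="columns")
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_manual_average_linkage_trace(self):
        # four unit vectors at angles 0°, 10°, 60°, 90°: cosine distances are
        # 1 − cos Δθ; UPGMA merges (0,1) at 0.0152, (2,3) at 0.1340, then the
        # two pairs at the average of the four cross-distances, 0.6707.
        ang = np.deg2rad([0.0, 10.0, 60.0, 90.0])
        m = pd.DataFrame(
            np.vstack([np.cos(ang), np.sin(ang)]), columns=list("abcd")
        )
        res = p.hier_cluster(m, axis="columns")
        Z = res.linkage
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert Z[0, 2] == pytest.approx(1 - np.cos(np.deg2rad(10)), abs=1e-9)
        assert set(Z[1, :2].astype(int)) == {2, 3}
        assert Z[1, 2] == pytest.approx(1 - np.cos(np.deg2rad(30)), abs=1e-9)
        cross = np.mean(
            [1 - np.cos(np.deg2rad(t)) for t in (60, 90, 50, 80)]
        )
        assert Z[2, 2] == pytest.approx(cross, abs=1e-9)

    def test_focus_rois_form_one_clade(self, dsp_experiment):
        exp, _ = dsp_experiment
        res = p.hier_cluster(p.hk_normalize(exp), axis="columns")
        idx = [i for i, r in enumerate(res.leaf_order) if r.startswith("focus")]
        assert max(idx) - min(idx) == len(idx) - 1  # contiguous in leaf order

    def test_topology_invariant_to_input_permutation(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.lognormal(2, 1, size=(30, 8)),
                         columns=[f"r{j}" for j in range(8)])
        res1 = p.hier_cluster(m, axis="columns")
        perm = rng.permutation(8)
        res2 = p.hier_cluster(m.iloc[:, perm], axis="columns")
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        c1 = pd.DataFrame(squareform(cophenet(res1.linkage)),
                          index=res1.labels, columns=res1.labels)
        c2 = pd.DataFrame(squareform(cophenet(res2.linkage)),
                          index=res2.labels, columns=res2.labels)
        assert np.allclose(c1.loc[res1.labels, res1.labels],
                           c2.loc[res1.labels, res1.labels])

    def test_zero_vector_item_rejected(self):
        m = pd.DataFrame([[1.0, 0.0], [1.0, 0.0]], columns=["a", "b"])
        with pytest.raises(DataError, match="b"):
            p.hier_cluster(m, axis="columns")

    def test_newick_export_contains_all_leaves(self, dsp_experiment):
        exp, _ = dsp_experiment
        res = p.hier_cluster(p.hk_normalize(exp), axis="columns")
        nwk = res.to_newick()
        assert nwk.endswith(";")
        for roi in exp.rois:
            assert roi in nwk

    def test_heatmap_scaling_bounded(self, dsp_experiment):
        exp, _ = dsp_experiment
        scaled = p.heatmap_scale(p.hk_normalize(exp)).to_numpy()
        assert scaled.min() >= -1.0 - 1e-12 and scaled.max() <= 1.0 + 1e-12


class TestPCA:
    def test_collinear_points_explained_by_pc1(self):
        t = np.linspace(1, 5, 6)
        norm = pd.DataFrame(2.0 ** np.vstack([t, 2 * t, -t]) - 1.0)
        res = p.pca(norm)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_variance_sums_to_one(self, dsp_experiment):
        exp, _ = dsp_experiment
        res = p.pca(p.hk_normalize(exp))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(17)
        norm = pd.DataFrame(rng.lognormal(2, 1, size=(10, 6)))
        res = p.pca(norm)
        X = np.log2(norm.to_numpy() + 1.0)
        Xc = X - X.mean(axis=1, keepdims=True)
        D = Xc.T  # ROIs × genes, feature-centered
        C = D.T @ D
        w, v = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        scores = D @ v
        for j in range(5):  # compare the non-degenerate components
            a = res.scores.to_numpy()[:, j]
            b = scores[:, j]
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_separation_of_roi_classes(self, dsp_experiment):
        exp, _ = dsp_experiment
        res = p.pca(p.hk_normalize(exp))
        pc1 = res.scores["PC1"]
        focus = [r for r in exp.rois if r.startswith("focus")]
        rest = [r for r in exp.rois if not r.startswith("focus")]
        # focus ROIs separate from the others along the top component
        assert (
            abs(pc1[focus].mean() - pc1[rest].mean())
            > 2 * max(pc1[focus].std(), pc1[rest].std())
        )


class TestGSEA:
    def test_five_gene_hand_trace(self):
        """Set = top-ranked gene, equal scores: the running sum peaks at
        1 − 1/N after position 1."""
        scores = pd.Series(1.0, index=[f"g{i}" for i in range(5)])
        res = p.gsea(scores, {"s": ["g0"]}, n_perm=200, seed=0)
        assert res.loc["s", "es"] == pytest.approx(1 - 1 / 5)

    def test_uniformly_spread_set_scores_near_zero(self):
        scores = pd.Series(1.0, index=[f"g{i:03d}" for i in range(100)])
        members = [f"g{i:03d}" for i in range(4, 100, 10)]
        res = p.gsea(scores, {"s": members}, n_perm=200, seed=0)
        assert abs(res.loc["s", "es"]) < 0.1

    def test_planted_top_set_enriched(self, dsp_experiment):
        exp, _ = dsp_experiment
        table = p.de_focus_vs_rest(exp, p.hk_normalize(exp))
        scores = d.rank_genes_for_gsea(table)
        top = scores.sort_values(ascending=False).index[:50]
        planted = list(top[::2][:20])  # 20-gene set inside the top 50 of 1825
        sets = {"planted": planted,
                **p.gen_gene_sets(list(scores.index), n_random_sets=4, seed=2)}
        res = p.gsea(scores, sets, n_perm=1000, seed=5)
        assert res.loc["planted", "nes"] > 0
        assert res.loc["planted", "fdr_q"] < 0.05

    def test_seeded_runs_are_bit_identical(self):
        rng = np.random.default_rng(8)
        scores = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
        sets = p.gen_gene_sets(list(scores.index), n_random_sets=3, seed=1)
        a = p.gsea(scores, sets, n_perm=300, seed=42)
        b = p.gsea(scores, sets, n_perm=300, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_sets_rejected(self):
        scores = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        with pytest.raises(DataError):
            p.gsea(scores, {"empty": ["zzz"]}, n_perm=100, seed=0)
        with pytest.raises(DataError):
            p.gsea(scores, {"everything": ["a", "b", "c"]}, n_perm=100, seed=0)

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg9\n")
        sets = d.read_gmt(path)
        assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g9"]}


class TestProbeCollapse:
    def test_geometric_mean_collapse(self):
        probes = pd.DataFrame(
            {"gene": ["A", "A", "B"], "r1": [2.0, 8.0, 5.0], "r2": [1.0, 1.0, 7.0]}
        )
        out = p.collapse_probes(probes)
        # log1p-mean-expm1 geometric-style mean of {2,8} and {1,1}
        expected_a_r1 = np.expm1(np.mean(np.log1p([2.0, 8.0])))
        assert out.loc["A", "r1"] == pytest.approx(expected_a_r1)
        assert out.loc["B", "r2"] == pytest.approx(7.0)
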