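"""Embedding, MNN batch correction, SNN-graph clustering, and marker
statistics."""

import igraph
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score, silhouette_score

import enspattern as ep
from enspattern.clustering import _mcfadden, _welch_one_sided


class TestPCAEmbed:
    def test_rank_one_input_second_singular_value_zero(self):
        a = np.outer(np.arange(1, 11.0), np.arange(1, 6.0))
        emb = ep.pca_embed(a, d=2, n_hvg=None)
        est = ep.HVGPCA(d=2, n_hvg=None).fit(a)
        assert est.singular_values_[1] <= 1e-10

    def test_variance_explained_nondecreasing_in_d(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (100, 50))
        # SVD oracle for total variance explained
        sv = np.linalg.svd(X - X.mean(0), compute_uv=False)
        prev = 0.0
        for d in (2, 5, 10, 20):
            emb = ep.pca_embed(X, d=d, n_hvg=None)
            ve = emb.explained_variance_ratio.sum()
            assert ve >= prev - 1e-12
            expected = (sv[:d] ** 2).sum() / (sv ** 2).sum()
            assert ve == pytest.approx(expected, rel=1e-8)
            prev = ve

    def test_d_exceeding_dims_rejected(self):
        with pytest.raises(ValueError):
            ep.pca_embed(np.random.default_rng(0).normal(size=(5, 4)), d=6)

    def test_hvg_selection_keeps_top_variance_genes(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 0.01, (50, 20))
        X[:, [3, 11]] += rng.normal(0, 5, (50, 2))
        est = ep.HVGPCA(d=2, n_hvg=2).fit(X)
        assert sorted(est.feature_index_) == [3, 11]


class TestMNNCorrect:
    def test_identical_batches_zero_correction(self):
        rng = np.random.default_rng(1)
        b = rng.normal(0, 1, (150, 8))
        out = ep.mnn_correct(np.vstack([b, b]),
                             np.array(["a"] * 150 + ["b"] * 150), k_mnn=15)
        assert np.abs(out[150:] - b).max() < 1e-8

    def test_constant_offset_recovered(self):
        rng = np.random.default_rng(2)
        b = rng.normal(0, 1, (200, 10))
        delta = np.full(10, 0.3)
        out = ep.mnn_correct(np.vstack([b, b + delta]),
                             np.array(["a"] * 200 + ["b"] * 200), k_mnn=20)
        mean_corr = (out[200:] - (b + delta)).mean(axis=0)
        assert np.abs(mean_corr + delta).max() < 0.01 * np.linalg.norm(delta)

    def test_single_batch_identity(self):
        rng = np.random.default_rng(3)
        b = rng.normal(0, 1, (60, 5))
        out = ep.mnn_correct(b, np.array(["a"] * 60), k_mnn=10)
        np.testing.assert_array_equal(out, b)

    def test_small_batch_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            ep.mnn_correct(np.zeros((30, 3)),
                           np.array(["a"] * 25 + ["b"] * 5), k_mnn=10)

    def test_reduces_batch_silhouette_on_shifted_cohort(self, filtered_cohort):
        filt, truth, mask, lognorm = filtered_cohort
        coords = ep.HVGPCA(d=20, n_hvg=2000).fit_transform(lognorm)
        batches = filt.obs["batch"].to_numpy()
        before = silhouette_score(coords, batches)
        corrected = ep.mnn_correct(coords, batches, k_mnn=20)
        after = silhouette_score(corrected, batches)
        assert after < before


class TestSNNGraph:
    def test_max_k_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 1, (12, 3))
        g = ep.snn_graph(coords, knn_k=11)
        assert g.ecount() == 12 * 11 // 2

    def test_separated_blobs_have_no_cross_edges(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(0, 1, (40, 4))
        blob2 = rng.normal(0, 1, (40, 4)) + 100.0
        g = ep.snn_graph(np.vstack([blob1, blob2]), knn_k=5)
        for e in g.es:
            assert (e.source < 40) == (e.target < 40)

    def test_weights_in_unit_interval_and_symmetric(self):
        rng = np.random.default_rng(4)
        g = ep.snn_graph(rng.normal(0, 1, (50, 5)), knn_k=8)
        w = np.array(g.es["weight"])
        assert np.all(w > 0) and np.all(w <= 1)
        assert not any(e.source == e.target for e in g.es)


class TestClusterGraph:
    def _two_cliques(self):
        g = igraph.Graph.Full(8) + igraph.Graph.Full(8)
        g.es["weight"] = [1.0] * g.ecount()
        return g

    # CPM keeps a unit-weight clique together only below gamma = 1, the
    # density of the clique itself; louvain's modularity has no such cap
    @pytest.mark.parametrize("method,resolution",
                             [("leiden", 0.01), ("leiden", 0.5),
                              ("louvain", 0.5), ("louvain", 1.0)])
    def test_two_disconnected_cliques_two_clusters(self, method, resolution):
        assign = ep.cluster_graph(self._two_cliques(), method, resolution,
                                  seed=0)
        assert assign.labels.max() + 1 == 2
        assert len(set(assign.labels[:8])) == 1
        assert len(set(assign.labels[8:])) == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        g = ep.snn_graph(rng.normal(0, 1, (80, 5)), knn_k=10)
        a = ep.cluster_graph(g, "leiden", 0.1, seed=42)
        b = ep.cluster_graph(g, "leiden", 0.1, seed=42)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_end_to_end_recovers_cell_types(self, filtered_cohort):
        filt, truth, mask, lognorm = filtered_cohort
        coords = ep.HVGPCA(d=50, n_hvg=2000).fit_transform(lognorm)
        coords = ep.mnn_correct(coords, filt.obs["batch"].to_numpy())
        labels = ep.SNNGraphClustering(knn_k=20, method="leiden",
                                       resolution=5e-3, seed=1
                                       ).fit_predict(coords)
        ari = adjusted_rand_score(filt.obs["cell_type"], labels)
        assert ari >= 0.8
        ann = ep.annotate_clusters(lognorm, labels,
                                   gene_names=list(filt.var_names))
        men_clusters = {c for c, lab in ann.items() if lab == "MEN"}
        true_men = set(labels[(filt.obs["lineage"] == "MEN-like").to_numpy()])
        assert men_clusters == true_men
        nen_clusters = {c for c, lab in ann.items() if lab == "NEN"}
        assert nen_clusters == set(
            labels[(filt.obs["cell_type"] == "NEN").to_numpy()])


class TestFindMarkers:
    def test_welch_t_closed_form(self):
        a = np.array([1.0, 2, 3])
        b = np.array([4.0, 5, 6])
        t, df, p = _welch_one_sided(a.mean(), a.var(ddof=1), 3,
                                    b.mean(), b.var(ddof=1), 3)
        assert t == pytest.approx(-3.6742, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p > 0.5     # one-sided "greater" against a larger group

    def test_constant_gene_never_a_marker(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 1, (40, 6))
        X[:, 0] = 3.0      # constant gene
        clusters = np.repeat([0, 1], 20)
        table = ep.find_markers(X, clusters, top_n=2)
        const_rows = table[table["gene"] == "g0"]
        assert (const_rows["combined_p"] == 1.0).all()
        assert not const_rows["is_marker"].any()

    def test_planted_marker_ranks_first_across_seeds(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            lam = np.full((100, 50), 1.0)
            lam[:50, 0] = 10.0    # 10x mean in cluster A
            mu = rng.gamma(10.0, lam / 10.0)
            X = np.log10(rng.poisson(mu) + 1.0)
            table = ep.find_markers(X, np.repeat([0, 1], 50))
            rank = table[(table["cluster"] == 0)
                         & (table["gene"] == "g0")]["rank"].iloc[0]
            hits += rank == 1
        assert hits >= 95

    def test_bh_qvalues_match_step_up_oracle(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042,
                      0.060, 0.074, 0.205, 0.212, 0.216])
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (20, 10))
        clusters = np.repeat([0, 1], 10)
        table = ep.find_markers(X, clusters)
        # oracle: direct step-up definition applied to the combined p's
        sub = table[table["cluster"] == 0].sort_values("rank")
        pv = sub["combined_p"].to_numpy()
        n = pv.size
        oracle = np.empty(n)
        for i in range(n):
            oracle[i] = min(min(pv[j] * n / (j + 1) for j in range(i, n)), 1.0)
        np.testing.assert_allclose(sub["bh_q"].to_numpy(), oracle, rtol=1e-12)

    def test_singleton_cluster_excluded_with_warning(self):
        X = np.random.default_rng(1).normal(0, 1, (9, 4))
        clusters = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2])
        with pytest.warns(UserWarning, match="excluded"):
            table = ep.find_markers(X, clusters)
        assert set(table["cluster"]) == {0, 1}


class TestPseudoR2:
    def test_constant_gene_zero(self):
        y = np.repeat([0, 1], 10)
        assert _mcfadden(y, np.full(20, 2.0)) == 0.0

    def test_perfect_separation_approaches_one(self):
        y = np.repeat([0, 1], 10)
        x = np.repeat([0.0, 5.0], 10)
        assert _mcfadden(y, x) >= 0.99

    def test_matches_direct_optimizer_oracle(self):
        from scipy.optimize import minimize
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 20)
        y = (x + rng.normal(0, 1, 20) > 0).astype(int)
        ridge = 1e-4

        def negloglik(params):
            b0, b1 = params
            z = b0 + b1 * x
            return np.sum(np.log1p(np.exp(-z * (2 * y - 1)))) \
                + 0.5 * ridge * b1 ** 2

        res = minimize(negloglik, [0.0, 0.0], method="BFGS")
        b0, b1 = res.x
        proba = 1 / (1 + np.exp(-(b0 + b1 * x)))
        ll_fit = np.sum(y * np.log(proba) + (1 - y) * np.log(1 - proba))
        p_hat = y.mean()
        ll_null = 20 * (p_hat * np.log(p_hat) + (1 - p_hat) * np.log(1 - p_hat))
        oracle = 1 - ll_fit / ll_null
        assert _mcfadden(y, x, ridge) == pytest.approx(oracle, abs=1e-4)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ep.marker_score_pseudo_r2(np.zeros((5, 2)), np.zeros(5))


class TestAnnotateClusters:
    def test_disjoint_signatures_fully_recovered(self):
        rng = np.random.default_rng(0)
        genes = ["Ret", "Sox10", "Ncam1", "Calcb", "Met", "Cdh3", "other"]
        X = rng.normal(0, 0.1, (60, 7))
        X[:20, 0] += 5          # NEN block
        X[20:40, 1:3] += 5      # glia block
        X[40:, 3:6] += 5        # MEN block
        clusters = np.repeat([0, 1, 2], 20)
        ann = ep.annotate_clusters(X, clusters, gene_names=genes)
        assert ann == {0: "NEN", 1: "neuroglia", 2: "MEN"}

    def test_uniform_expression_unassigned(self):
        X = np.full((30, 6), 1.0)
        genes = ["Ret", "Sox10", "Ncam1", "Calcb", "Met", "Cdh3"]
        ann = ep.annotate_clusters(X, np.repeat([0, 1], 15), gene_names=genes)
        assert set(ann.values()) == {"unassigned"}

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            ep.annotate_clusters(np.zeros((4, 2)), np.zeros(4),
                                 signature_sets={"x": set()},
                                 gene_names=["a", "b"])
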