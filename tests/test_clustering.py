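"""Normalization, HVG, PCA, graph building/fusion, Leiden, and markers."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import stereopipe as spp
from stereopipe.clustering import (
    NeighborGraph,
    Partition,
    leiden_partition,
    leiden_target_clusters,
)


class TestNormalize:
    def test_lognorm_closed_form(self):
        X = np.array([[10_000, 0]])
        norm, kept = spp.normalize(X, "lognorm")
        assert norm[0, 0] == pytest.approx(np.log1p(10_000))
        assert norm[0, 1] == 0.0

    def test_all_zero_gene_stays_zero(self):
        X = np.array([[5, 0], [3, 0]])
        norm, _ = spp.normalize(X, "lognorm")
        assert (norm[:, 1] == 0).all()

    def test_zero_total_rows_dropped_with_warning(self):
        X = np.array([[1, 2], [0, 0], [3, 4]])
        with pytest.warns(UserWarning, match="zero-total"):
            norm, kept = spp.normalize(X)
        assert norm.shape[0] == 2 and kept.tolist() == [0, 2]

    def test_pearson_residuals_vanish_for_proportional_gene(self, rng):
        """A gene exactly proportional to row totals has ~0 residuals."""
        base = rng.integers(1, 50, size=(30, 5))
        X = np.hstack([base, base.sum(axis=1, keepdims=True)])  # gene 5 = total/2
        norm, _ = spp.normalize(X, "pearson_residual")
        assert np.abs(norm[:, 5]).max() < 1e-9

    def test_pearson_residuals_clipped(self):
        X = np.eye(5, dtype=int) * 1000 + 1
        norm, _ = spp.normalize(X, "pearson_residual")
        assert np.abs(norm).max() <= np.sqrt(5) + 1e-12

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            spp.normalize(np.ones((2, 2)), "quantile")


class TestHVG:
    def test_planted_markers_rank_in_top_set(self, small_bins):
        bins, labels, truth = small_bins
        norm, _ = spp.normalize(np.asarray(bins.X.todense()))
        hvg = spp.select_hvg(norm, bins.var_names, 30)
        selected = set(np.asarray(bins.var_names)[hvg])
        assert set(truth.markers["gene"]) <= selected

    def test_constant_gene_never_beats_varying(self, rng):
        X = np.column_stack([np.full(20, 5.0), rng.normal(5, 2, 20)])
        hvg = spp.select_hvg(X, ["const", "vary"], 1)
        assert list(np.array(["const", "vary"])[hvg]) == ["vary"]

    def test_all_genes_when_n_top_equals_n_genes(self, rng):
        X = rng.normal(size=(10, 4))
        assert len(spp.select_hvg(X, list("abcd"), 4)) == 4

    def test_validation(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            spp.select_hvg(X, list("abcd"), 0)
        with pytest.raises(ValueError):
            spp.select_hvg(X, list("abcd"), 5)


class TestPCA:
    def test_planar_data_truncated_with_warning(self, rng):
        basis = rng.normal(size=(2, 6))
        X = rng.normal(size=(50, 2)) @ basis  # rank 2
        with pytest.warns(UserWarning, match="rank"):
            res = spp.pca_reduce(X, n_components=5)
        assert res.embedding.shape[1] == 2

    def test_explained_variance_non_increasing(self, rng):
        X = rng.normal(size=(40, 10)) * np.arange(1, 11)
        res = spp.pca_reduce(X, n_components=8)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_reconstruction_error_decreases_with_components(self, rng):
        X = rng.normal(size=(30, 12)) * np.linspace(3, 0.2, 12)
        Xc = X - X.mean(axis=0)
        errs = []
        for k in (2, 5, 9):
            res = spp.pca_reduce(X, n_components=k)
            recon = res.embedding @ res.components
            errs.append(np.linalg.norm(Xc - recon))
        assert errs[0] > errs[1] > errs[2]

    def test_deterministic_sign_convention(self, rng):
        X = rng.normal(size=(25, 6))
        a = spp.pca_reduce(X, 3)
        b = spp.pca_reduce(X.copy(), 3)
        assert np.allclose(a.embedding, b.embedding)
        for row in a.components:
            assert row[np.argmax(np.abs(row))] > 0


class TestGraphs:
    def test_two_far_blobs_have_no_cross_edges(self, rng):
        blob1 = rng.normal(0, 0.1, size=(20, 3))
        blob2 = rng.normal(50, 0.1, size=(20, 3))
        g = spp.knn_graph_expression(np.vstack([blob1, blob2]), k=5)
        A = g.adjacency.toarray()
        assert A[:20, 20:].sum() == 0

    def test_degree_at_least_k_after_union(self, rng):
        pts = rng.normal(size=(30, 4))
        g = spp.knn_graph_expression(pts, k=7)
        assert (g.degrees() >= 7).all()
        assert (g.adjacency != g.adjacency.T).nnz == 0  # symmetric
        assert g.adjacency.diagonal().sum() == 0  # no self loops

    def test_duplicate_points_deterministic(self):
        pts = np.zeros((6, 2))
        a = spp.knn_graph_expression(pts, k=2).adjacency.toarray()
        b = spp.knn_graph_expression(pts.copy(), k=2).adjacency.toarray()
        assert np.array_equal(a, b)

    def test_spatial_grid_interior_neighbors(self):
        xx, yy = np.meshgrid(np.arange(5), np.arange(5))
        coords = np.column_stack([xx.ravel(), yy.ravel()])
        g = spp.knn_graph_spatial(coords, k=4)
        center = 12  # (2, 2)
        neigh = set(g.adjacency[center].indices)
        # the 4 rook-adjacent bins are the nearest at distance 1
        assert {7, 11, 13, 17} <= neigh

    def test_full_grid_graph_connected(self):
        import scipy.sparse.csgraph as csgraph

        for w, h in [(4, 4), (7, 3), (2, 9)]:
            xx, yy = np.meshgrid(np.arange(w), np.arange(h))
            coords = np.column_stack([xx.ravel(), yy.ravel()])
            g = spp.knn_graph_spatial(coords, k=2)
            n, _ = csgraph.connected_components(g.adjacency)
            assert n == 1

    def test_single_row_path_like(self):
        coords = np.column_stack([np.arange(10), np.zeros(10)])
        g = spp.knn_graph_spatial(coords, k=2)
        assert (g.degrees() >= 2).all()

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            spp.knn_graph_expression(rng.normal(size=(5, 2)), k=5)


class TestFusion:
    def _toy_graphs(self):
        A = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=float))
        B = sp.csr_matrix(np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float))
        return NeighborGraph(A, "spatial"), NeighborGraph(B, "expression")

    def test_alpha_limits_reproduce_inputs(self):
        gs, ge = self._toy_graphs()
        assert (spp.fuse_graphs(gs, ge, 1.0).adjacency != gs.adjacency).nnz == 0
        assert (spp.fuse_graphs(gs, ge, 0.0).adjacency != ge.adjacency).nnz == 0

    def test_weight_formula(self):
        gs, ge = self._toy_graphs()
        F = spp.fuse_graphs(gs, ge, 0.5).adjacency.toarray()
        assert F[0, 1] == 1.0  # in both: 0.5*1 + 0.5*1
        assert F[0, 2] == 0.5  # expression only
        assert np.array_equal(F, F.T)

    def test_node_mismatch_rejected(self):
        gs, ge = self._toy_graphs()
        small = NeighborGraph(sp.csr_matrix((2, 2)), "expression")
        with pytest.raises(ValueError):
            spp.fuse_graphs(gs, small)


def _two_cliques_graph(n=10):
    A = np.zeros((2 * n, 2 * n))
    A[:n, :n] = 1
    A[n:, n:] = 1
    np.fill_diagonal(A, 0)
    return NeighborGraph(sp.csr_matrix(A), "expression")


class TestLeiden:
    def test_disconnected_cliques_found_exactly(self):
        g = _two_cliques_graph()
        for res in (0.1, 0.5, 1.0):
            part = leiden_partition(g, resolution=res, seed=0)
            assert part.n_clusters == 2
            labels = part.labels
            assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1

    def test_deterministic_under_seed(self, small_bins):
        bins, _, _ = small_bins
        norm, _ = spp.normalize(np.asarray(bins.X.todense()))
        emb = spp.pca_reduce(norm, 10).embedding
        g = spp.knn_graph_expression(emb, k=10)
        a = leiden_partition(g, 1.0, seed=7)
        b = leiden_partition(g, 1.0, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_cluster_count_grows_with_resolution(self, small_bins):
        bins, _, _ = small_bins
        norm, _ = spp.normalize(np.asarray(bins.X.todense()))
        emb = spp.pca_reduce(norm, 10).embedding
        g = spp.knn_graph_expression(emb, k=10)
        counts = [leiden_partition(g, r, seed=0).n_clusters for r in (0.01, 0.5, 3.0)]
        assert counts[0] <= counts[1] <= counts[2]

    def test_target_cluster_bisection(self):
        g = _two_cliques_graph()
        part = leiden_target_clusters(g, 2, seed=0)
        assert part.n_clusters == 2

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            leiden_partition(NeighborGraph(sp.csr_matrix((0, 0)), "fused"))

    def test_labels_contiguous_from_zero(self, small_bins):
        bins, _, _ = small_bins
        norm, _ = spp.normalize(np.asarray(bins.X.todense()))
        emb = spp.pca_reduce(norm, 10).embedding
        g = spp.knn_graph_expression(emb, k=10)
        part = leiden_partition(g, 2.0, seed=1)
        assert set(part.labels) == set(range(part.n_clusters))


class TestMarkers:
    def test_planted_markers_found_with_higher_pct(self, small_bins):
        bins, labels, truth = small_bins
        X = np.asarray(bins.X.todense())
        table = spp.find_markers(X, labels, bins.var_names)
        deg = spp.deg_filter(table)
        for gene, region in truth.markers.itertuples(index=False):
            rows = deg[(deg["cluster"] == region) & (deg["gene"] == gene)]
            assert len(rows) == 1
            assert rows.iloc[0]["pct_in"] > rows.iloc[0]["pct_out"]

    def test_min_pct_excludes_rare_genes(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(2, size=(100, 3))
        # gene 2 expressed in ~4% of both groups
        X[:, 2] = (rng.random(100) < 0.04).astype(int)
        labels = np.repeat([0, 1], 50)
        table = spp.find_markers(X, labels, ["a", "b", "rare"], min_pct=0.05)
        assert "rare" not in set(table["gene"])

    def test_singleton_cluster_skipped(self, rng):
        X = rng.poisson(3, size=(21, 4)) + 1
        labels = np.array([0] * 10 + [1] * 10 + [2])
        with pytest.warns(UserWarning, match="size 1"):
            table = spp.find_markers(X, labels, list("abcd"))
        assert 2 not in set(table["cluster"])

    def test_wilcoxon_p_matches_permutation_oracle(self, rng):
        """Asymptotic rank-sum p agrees with a permutation null on one gene."""
        x = np.concatenate([rng.poisson(3, 40), rng.poisson(4, 40)])
        labels = np.repeat([0, 1], 40)
        X = np.column_stack([x, rng.poisson(3, 80)]) + 1
        table = spp.find_markers(X, labels, ["g", "h"], min_pct=0.0)
        p_asym = table[(table.cluster == 0) & (table.gene == "g")]["pvalue"].iloc[0]
        # permutation oracle on the same normalized statistic
        from scipy.stats import rankdata

        norm, _ = spp.normalize(X)
        v = norm[:, 0]
        obs = rankdata(v)[:40].sum()
        null = []
        for _ in range(3000):
            perm = rng.permutation(v)
            null.append(rankdata(perm)[:40].sum())
        null = np.array(null)
        p_perm = np.mean(np.abs(null - null.mean()) >= abs(obs - null.mean()))
        assert abs(p_asym - p_perm) < 0.05


class TestDegFilter:
    def _row(self, log2fc, padj, pct_in, pct_out):
        return pd.DataFrame(
            [[0, "g", log2fc, padj / 2, padj, pct_in, pct_out]],
            columns=["cluster", "gene", "log2fc", "pvalue", "padj", "pct_in", "pct_out"],
        )

    def test_passing_row_kept(self):
        assert len(spp.deg_filter(self._row(np.log2(3), 0.01, 0.3, 0.1))) == 1

    def test_fold_change_exactly_two_dropped(self):
        assert len(spp.deg_filter(self._row(1.0, 0.01, 0.3, 0.1))) == 0

    def test_delta_pct_exactly_point_one_dropped(self):
        assert len(spp.deg_filter(self._row(np.log2(5), 0.04, 0.2, 0.1))) == 0

    def test_padj_boundary_strict(self):
        assert len(spp.deg_filter(self._row(np.log2(5), 0.05, 0.3, 0.1))) == 0


def test_fused_clustering_beats_expression_only(small_bins):
    """Spatial smoothing helps recover stripe regions on the small tissue."""
    from sklearn.metrics import adjusted_rand_score

    bins, labels, _ = small_bins
    res = spp.spatially_constrained_clustering(bins, n_clusters=5, seed=0)
    truth = labels[res["kept_rows"]]
    ari_f = adjusted_rand_score(truth, res["partition_fused"].labels)
    ari_e = adjusted_rand_score(truth, res["partition_expression"].labels)
    assert ari_f >= 0.8
    assert ari_f >= ari_e
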