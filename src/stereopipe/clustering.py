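"""Spatially constrained clustering of bins (or cells) and marker calling.

The pipeline: normalize counts, select highly variable genes, embed with
PCA (30 components), build a k-nearest-neighbour graph in expression space
and another on the bin centroids, fuse the two graphs as a weighted union,
and partition the fused graph with the Leiden algorithm. Mixing spatial
adjacency into the graph biases communities toward spatially contiguous,
transcriptionally coherent domains. Cluster markers come from one-vs-rest
Wilcoxon rank-sum tests with Benjamini-Hochberg correction, and the DEG
filter applies the strict fold-change / adjusted-p / positive-ratio rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


# -- normalization -------------------------------------------------------


def normalize(
    counts,
    method: str = "lognorm",
    scale_factor: float = 1e4,
    theta: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a cells/bins x genes count matrix.

    ``lognorm``: log1p(count / row_total * scale_factor).
    ``pearson_residual``: analytic Pearson residuals of an NB model with
    per-gene mean proportional to the row total and fixed size ``theta``
    (100), clipped at +-sqrt(n_rows) — a fully specified variance
    stabilizer with the same intent as regularized NB regression.

    Zero-total rows are dropped with a warning; returns (matrix, kept_rows).
    """
    X = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=np.float64)
    totals = X.sum(axis=1)
    kept = np.flatnonzero(totals > 0)
    if len(kept) < X.shape[0]:
        warnings.warn(
            f"dropped {X.shape[0] - len(kept)} zero-total rows before normalization",
            stacklevel=2,
        )
        X = X[kept]
        totals = totals[kept]
    if method == "lognorm":
        return np.log1p(X / totals[:, None] * scale_factor), kept
    if method == "pearson_residual":
        gene_tot = X.sum(axis=0)
        grand = totals.sum()
        mu = np.outer(totals, gene_tot) / grand
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = (X - mu) / np.sqrt(mu + mu**2 / theta)
        resid[~np.isfinite(resid)] = 0.0
        clip = np.sqrt(X.shape[0])
        return np.clip(resid, -clip, clip), kept
    raise ValueError(f"unknown normalization method {method!r}")


def select_hvg(normalized: np.ndarray, gene_names, n_top: int) -> np.ndarray:
    """Indices of the ``n_top`` most dispersed genes.

    Dispersion (var/mean) is computed on the de-logged normalized values:
    on the log scale high-mean genes are compressed and genuine
    between-group variability would rank *below* shot noise. Ties are
    broken by lexicographic gene id so the selection is deterministic;
    constant genes (zero variance) rank last.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if normalized.shape[1] < n_top:
        raise ValueError("fewer genes than n_top")
    gene_names = np.asarray(gene_names, dtype=object)
    delogged = np.expm1(normalized)
    mean = delogged.mean(axis=0)
    var = delogged.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    disp[var == 0] = -np.inf
    order = np.lexsort((gene_names, -disp))
    return np.sort(order[:n_top])


@dataclass
class PCAResult:
    embedding: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_reduce(normalized: np.ndarray, n_components: int = 30) -> PCAResult:
    """Centered PCA with a deterministic sign convention.

    Each component is flipped so its largest-magnitude loading is
    positive. Degenerate rank yields fewer components with a warning.
    """
    n, g = normalized.shape
    if n_components > min(n, g):
        raise ValueError("n_components exceeds min(n_samples, n_genes)")
    pca = PCA(n_components=n_components, svd_solver="full")
    emb = pca.fit_transform(normalized)
    ev = pca.explained_variance_
    tol = max(ev[0], 1.0) * 1e-12 if len(ev) else 0.0
    rank = int((ev > tol).sum())
    if rank < n_components:
        warnings.warn(
            f"data rank {rank} < requested {n_components}; truncating", stacklevel=2
        )
        emb = emb[:, :rank]
        comps = pca.components_[:rank]
        ratio = pca.explained_variance_ratio_[:rank]
    else:
        comps = pca.components_
        ratio = pca.explained_variance_ratio_
    for j in range(comps.shape[0]):
        i = int(np.argmax(np.abs(comps[j])))
        if comps[j, i] < 0:
            comps[j] = -comps[j]
            emb[:, j] = -emb[:, j]
    return PCAResult(emb, comps, ratio)


# -- graphs --------------------------------------------------------------


@dataclass
class NeighborGraph:
    """Symmetric weighted graph over bins/cells as a CSR adjacency."""

    adjacency: sp.csr_matrix
    kind: str

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray((self.adjacency > 0).sum(axis=1)).ravel()


def _knn_indices(points: np.ndarray, k: int) -> np.ndarray:
    """Exact kNN with deterministic (distance, index) tie-breaking."""
    n = points.shape[0]
    if n <= 4096:
        d2 = (
            (points**2).sum(1)[:, None]
            + (points**2).sum(1)[None, :]
            - 2 * points @ points.T
        )
        np.fill_diagonal(d2, np.inf)
        d2 = np.round(d2, 9)  # collapse float fuzz so ties break by index
        idx = np.lexsort((np.tile(np.arange(n), (n, 1)), d2), axis=1)
        return idx[:, :k]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    _, idx = nn.kneighbors(points)
    out = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        out[i] = row
    return out


def _knn_graph(points: np.ndarray, k: int, kind: str) -> NeighborGraph:
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    idx = _knn_indices(np.asarray(points, dtype=np.float64), k)
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    A = sp.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)  # symmetrize by union, binary weights
    A.setdiag(0)
    A.eliminate_zeros()
    return NeighborGraph(A, kind)


def knn_graph_expression(embedding: np.ndarray, k: int = 15) -> NeighborGraph:
    """Union-symmetrized kNN graph on the PCA embedding (Euclidean)."""
    return _knn_graph(embedding, k, "expression")


def knn_graph_spatial(coordinates: np.ndarray, k: int = 6) -> NeighborGraph:
    """Union-symmetrized kNN graph on (bin_x, bin_y) centroids."""
    return _knn_graph(coordinates, k, "spatial")


def fuse_graphs(
    spatial: NeighborGraph, expression: NeighborGraph, alpha: float = 0.5
) -> NeighborGraph:
    """Weighted union of the spatial and expression graphs.

    Edge weight = alpha * w_spatial + (1 - alpha) * w_expression, with an
    absent edge contributing 0; alpha=1 returns the spatial graph, alpha=0
    the expression graph.
    """
    if spatial.adjacency.shape != expression.adjacency.shape:
        raise ValueError("graphs have different node sets")
    A = alpha * spatial.adjacency + (1 - alpha) * expression.adjacency
    A = sp.csr_matrix(A)
    A.eliminate_zeros()
    return NeighborGraph(A, "fused")


# -- Leiden --------------------------------------------------------------


@dataclass
class Partition:
    labels: np.ndarray
    resolution: float
    seed: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def leiden_partition(
    graph: NeighborGraph, resolution: float = 1.0, seed: int = 0
) -> Partition:
    """Leiden community detection (RB-modularity) on a NeighborGraph.

    Deterministic under a fixed seed; labels are relabelled to contiguous
    integers ordered by first occurrence.
    """
    import igraph as ig
    import leidenalg as la

    A = sp.triu(graph.adjacency, k=1).tocoo()
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    g = ig.Graph(n=n, edges=list(zip(A.row.tolist(), A.col.tolist())))
    part = la.find_partition(
        g,
        la.RBConfigurationVertexPartition,
        weights=A.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    _, labels = np.unique(raw, return_inverse=True)
    # reorder so labels appear in first-occurrence order
    order = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return Partition(out, resolution, seed)


def leiden_target_clusters(
    graph: NeighborGraph,
    n_clusters: int,
    seed: int = 0,
    resolution_bounds: tuple[float, float] = (1e-5, 10.0),
    max_iter: int = 25,
) -> Partition:
    """Bisection on the resolution parameter toward a requested cluster count.

    Cluster count grows (stochastically) with resolution under the
    RB-modularity objective; the search returns the partition whose count
    is closest to the target, preferring exact hits.
    """
    lo, hi = resolution_bounds
    best: Partition | None = None
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # geometric bisection: resolution spans decades
        part = leiden_partition(graph, resolution=mid, seed=seed)
        k = part.n_clusters
        if best is None or abs(k - n_clusters) < abs(best.n_clusters - n_clusters):
            best = part
        if k == n_clusters:
            return part
        if k < n_clusters:
            lo = mid
        else:
            hi = mid
    return best


# -- markers -------------------------------------------------------------


def find_markers(
    counts,
    labels: np.ndarray,
    gene_names,
    min_pct: float = 0.05,
    pseudocount: float = 1e-9,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker test per cluster.

    Genes enter a cluster's test family when max(pct_in, pct_out) >= min_pct
    (fraction of bins/cells with a nonzero count). P-values are BH-adjusted
    within each cluster's family; log2FC compares the de-logged means of
    the log-normalized values with a pseudocount. Clusters of size 1 are
    skipped with a warning.
    """
    X = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=np.float64)
    labels = np.asarray(labels)
    gene_names = np.asarray(gene_names, dtype=object)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for marker calling")
    norm, kept = normalize(X, method="lognorm")
    if len(kept) != X.shape[0]:
        X = X[kept]
        labels = labels[kept]
    expressed = X > 0
    exp_norm = np.expm1(norm)
    rows = []
    for c in uniq:
        in_mask = labels == c
        n_in = int(in_mask.sum())
        if n_in < 2:
            warnings.warn(f"cluster {c} has size {n_in}; skipped", stacklevel=2)
            continue
        out_mask = ~in_mask
        pct_in = expressed[in_mask].mean(axis=0)
        pct_out = expressed[out_mask].mean(axis=0)
        tested = np.flatnonzero(np.maximum(pct_in, pct_out) >= min_pct)
        if not len(tested):
            continue
        stat = scipy.stats.mannwhitneyu(
            norm[in_mask][:, tested],
            norm[out_mask][:, tested],
            alternative="two-sided",
            method="asymptotic",
            axis=0,
        )
        pvals = np.atleast_1d(stat.pvalue)
        padj = scipy.stats.false_discovery_control(pvals, method="bh")
        mean_in = exp_norm[in_mask][:, tested].mean(axis=0)
        mean_out = exp_norm[out_mask][:, tested].mean(axis=0)
        log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
        for j, g in enumerate(tested):
            rows.append(
                (
                    c,
                    gene_names[g],
                    float(log2fc[j]),
                    float(pvals[j]),
                    float(padj[j]),
                    float(pct_in[g]),
                    float(pct_out[g]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["cluster", "gene", "log2fc", "pvalue", "padj", "pct_in", "pct_out"],
    )


def deg_filter(
    markers: pd.DataFrame,
    min_fold_change: float = 2.0,
    max_padj: float = 0.05,
    min_delta_pct: float = 0.1,
) -> pd.DataFrame:
    """Strict DEG rule: FC > 2, adjusted p < 0.05, (pct_in - pct_out) > 0.1.

    All three inequalities are strict: a row at exactly FC 2 or delta-pct
    0.1 is dropped.
    """
    keep = (
        (markers["log2fc"] > np.log2(min_fold_change))
        & (markers["padj"] < max_padj)
        & ((markers["pct_in"] - markers["pct_out"]) > min_delta_pct)
    )
    return markers[keep].reset_index(drop=True)


# -- end-to-end convenience ----------------------------------------------


def spatially_constrained_clustering(
    bins,
    n_hvg: int = 2000,
    n_components: int = 30,
    k_expression: int = 15,
    k_spatial: int = 6,
    alpha: float = 0.5,
    resolution: float | None = 1.0,
    n_clusters: int | None = None,
    seed: int = 0,
) -> dict:
    """Run the full bin-clustering recipe on a BinMatrix AnnData.

    Returns a dict with the fused-graph partition plus the expression-only
    partition, the graphs, and the PCA embedding. When ``n_clusters`` is
    given the Leiden resolution is found by bisection (both partitions use
    the same procedure); otherwise ``resolution`` is used directly.
    """
    X = bins.X
    coords = bins.obs[["bin_x", "bin_y"]].to_numpy(dtype=np.float64)
    norm, kept = normalize(X, method="lognorm")
    coords = coords[kept]
    n_top = min(n_hvg, norm.shape[1])
    hvg = select_hvg(norm, bins.var_names, n_top)
    n_comp = min(n_components, norm.shape[0] - 1, len(hvg))
    pca = pca_reduce(norm[:, hvg], n_components=n_comp)
    g_expr = knn_graph_expression(pca.embedding, k=min(k_expression, norm.shape[0] - 1))
    g_spatial = knn_graph_spatial(coords, k=min(k_spatial, norm.shape[0] - 1))
    g_fused = fuse_graphs(g_spatial, g_expr, alpha=alpha)
    if n_clusters is not None:
        part_fused = leiden_target_clusters(g_fused, n_clusters, seed=seed)
        part_expr = leiden_target_clusters(g_expr, n_clusters, seed=seed)
    else:
        part_fused = leiden_partition(g_fused, resolution=resolution, seed=seed)
        part_expr = leiden_partition(g_expr, resolution=resolution, seed=seed)
    return {
        "kept_rows": kept,
        "hvg": hvg,
        "pca": pca,
        "graph_expression": g_expr,
        "graph_spatial": g_spatial,
        "graph_fused": g_fused,
        "partition_fused": part_fused,
        "partition_expression": part_expr,
    }
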