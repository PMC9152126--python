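"""Rank-based regulon activity (AUCell-style) and region enrichment.

A regulon is a transcription factor with its target-gene set. Its activity
in one bin is the area under the target recovery curve within the top
fraction (default 5%) of that bin's gene ranking: genes are ranked by
expression descending (ties by a fixed gene order), the recovery curve
counts targets among the top ranks, and the area is normalized by the
saturated rectangle so the score lives in [0, 1]. Being rank-based, the
score is invariant under any monotone transform of the expression values.

Region enrichment of a regulon is the mean activity of each region minus
the mean activity over all bins; regulons whose enrichment stays below a
floor (0.1) in every region are dropped as uninformative.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp


def _rank_positions(X: np.ndarray) -> np.ndarray:
    """0-based rank of each gene per row, descending expression, ties by column."""
    order = np.argsort(-X, axis=1, kind="stable")
    pos = np.empty_like(order)
    rows = np.arange(X.shape[0])[:, None]
    pos[rows, order] = np.arange(X.shape[1])[None, :]
    return pos


def aucell_score(
    expression_row: np.ndarray,
    target_mask: np.ndarray,
    top_fraction: float = 0.05,
) -> float:
    """AUC of the target recovery curve within the top-ranked window.

    ``target_mask`` flags the regulon's targets among the gene universe.
    With window W = ceil(top_fraction * n_genes) and k targets, the score
    is sum over targets at 0-based rank p < W of (W - p), divided by
    min(k, W) * W; all-top-ranked targets give 1 - (k-1)/(2W), no target
    in the window gives 0.
    """
    X = np.asarray(expression_row, dtype=np.float64).reshape(1, -1)
    mask = np.asarray(target_mask, dtype=bool)
    k = int(mask.sum())
    if k == 0:
        raise ValueError("no targets present in the gene universe")
    n_genes = X.shape[1]
    window = math.ceil(top_fraction * n_genes)
    pos = _rank_positions(X)[0]
    in_window = mask & (pos < window)
    area = float(np.sum(window - pos[in_window]))
    return area / (min(k, window) * window)


def aucell_matrix(
    expression,
    gene_names,
    regulons: dict[str, list[str]],
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Score every regulon in every bin; returns a bins x regulons frame.

    Targets absent from the gene universe are dropped with a warning, and
    a regulon with no remaining targets is dropped entirely.
    """
    X = np.asarray(
        expression.todense() if sp.issparse(expression) else expression,
        dtype=np.float64,
    )
    genes = pd.Index(gene_names)
    window = math.ceil(top_fraction * len(genes))
    pos = _rank_positions(X)
    scores = {}
    for name in sorted(regulons):
        idx = genes.get_indexer(regulons[name])
        missing = int((idx < 0).sum())
        if missing:
            warnings.warn(
                f"regulon {name}: {missing} target(s) absent from the universe",
                stacklevel=2,
            )
        idx = idx[idx >= 0]
        if not len(idx):
            warnings.warn(f"regulon {name} has no targets in the universe; dropped",
                          stacklevel=2)
            continue
        p = pos[:, idx]
        area = np.where(p < window, window - p, 0).sum(axis=1).astype(np.float64)
        scores[name] = area / (min(len(idx), window) * window)
    out = pd.DataFrame(scores, index=getattr(expression, "obs_names", None))
    out.index.name = "bin"
    return out


def region_enrichment(
    activity: pd.DataFrame,
    region_labels,
    min_enrichment: float = 0.1,
) -> tuple[pd.DataFrame, list[str]]:
    """Region-mean activity minus global-mean activity, with a retention floor.

    E(region, regulon) = mean activity over the region's bins minus the
    mean over all bins (unweighted). Regulons whose maximum enrichment over
    regions is below ``min_enrichment`` are dropped. Returns the filtered
    regions x regulons table and the list of dropped regulons. The
    bin-count-weighted mean of E over regions is identically zero.
    """
    labels = pd.Series(np.asarray(region_labels), index=activity.index, name="region")
    if labels.isna().any():
        raise ValueError("every bin must carry a region label")
    overall = activity.mean(axis=0)
    table = activity.groupby(labels).mean() - overall
    table.index.name = "region"
    max_e = table.max(axis=0)
    dropped = sorted(table.columns[max_e < min_enrichment])
    return table.drop(columns=dropped), dropped
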