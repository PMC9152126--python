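"""Square binning of spot-level counts and per-bin / replicate QC.

A "bin N" aggregates N x N adjacent spots by floor division of the spot
coordinates, anchored at the grid origin, so bin 50 on a 500 nm-pitch chip
has a 25 um physical side. Binning is exactly UMI-conserving.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from anndata import AnnData

from .gem_io import SpotMatrix


def bin_physical_side_um(bin_size: int, pitch_nm: float) -> float:
    """Physical side length of a square bin, in micrometers."""
    return bin_size * pitch_nm / 1000.0


def bin_spots(matrix: SpotMatrix, bin_size: int) -> AnnData:
    """Aggregate a SpotMatrix into bins of ``bin_size`` x ``bin_size`` spots.

    Returns a bins x genes AnnData with integer CSR counts; ``obs`` carries
    (bin_x, bin_y) = floor(x / bin_size), floor(y / bin_size). Bins with no
    counts are absent. ``uns`` records bin_size, pitch and physical side.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = matrix.records
    bx = df["x"].to_numpy() // bin_size
    by = df["y"].to_numpy() // bin_size
    bins = pd.DataFrame({"bin_x": bx, "bin_y": by, "geneID": df["geneID"],
                         "MIDCount": df["MIDCount"]})
    bin_index = pd.MultiIndex.from_arrays([bx, by]).unique().sortlevel()[0]
    genes = pd.Index(sorted(df["geneID"].unique()), name="gene")
    row = bin_index.get_indexer(pd.MultiIndex.from_arrays([bx, by]))
    col = genes.get_indexer(df["geneID"])
    X = sp.coo_matrix(
        (df["MIDCount"].to_numpy(), (row, col)),
        shape=(len(bin_index), len(genes)),
        dtype=np.int64,
    ).tocsr()
    X.sum_duplicates()
    obs = pd.DataFrame(
        {
            "bin_x": bin_index.get_level_values(0).astype(np.int64),
            "bin_y": bin_index.get_level_values(1).astype(np.int64),
        }
    )
    obs.index = [f"bin_{x}_{y}" for x, y in zip(obs["bin_x"], obs["bin_y"])]
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    adata.uns["bin_size"] = bin_size
    adata.uns["pitch_nm"] = matrix.pitch_nm
    adata.uns["bin_side_um"] = bin_physical_side_um(bin_size, matrix.pitch_nm)
    return adata


def bins_to_spot_matrix(bins: AnnData) -> SpotMatrix:
    """Re-express a BinMatrix as a GEM-style SpotMatrix on bin coordinates."""
    coo = sp.coo_matrix(bins.X)
    df = pd.DataFrame(
        {
            "geneID": bins.var_names.to_numpy()[coo.col],
            "x": bins.obs["bin_x"].to_numpy()[coo.row],
            "y": bins.obs["bin_y"].to_numpy()[coo.row],
            "MIDCount": coo.data.astype(np.int64),
        }
    )
    df = df[df["MIDCount"] > 0]
    return SpotMatrix(df.reset_index(drop=True), pitch_nm=float(bins.uns["pitch_nm"]))


def bin_qc(bins: AnnData) -> tuple[pd.DataFrame, dict]:
    """Per-bin UMI and gene counts plus mean/median summaries."""
    X = sp.csr_matrix(bins.X)
    qc = pd.DataFrame(
        {
            "bin_x": bins.obs["bin_x"].to_numpy(),
            "bin_y": bins.obs["bin_y"].to_numpy(),
            "n_umi": np.asarray(X.sum(axis=1)).ravel().astype(np.int64),
            "n_genes": np.asarray((X > 0).sum(axis=1)).ravel().astype(np.int64),
        },
        index=bins.obs_names,
    )
    if len(qc):
        summary = {
            "n_bins": int(len(qc)),
            "mean_umi": float(qc["n_umi"].mean()),
            "median_umi": float(qc["n_umi"].median()),
            "mean_genes": float(qc["n_genes"].mean()),
            "median_genes": float(qc["n_genes"].median()),
        }
    else:
        summary = {"n_bins": 0}
    return qc, summary


def replicate_correlation(
    bins_a: AnnData, bins_b: AnnData, log_transform: bool = True
) -> dict:
    """Pearson correlation of per-gene pseudobulk between two sections.

    Pseudobulk is the per-gene total UMI over the union gene universe
    (missing genes count 0); the correlation is computed on log1p totals
    by default. Rejects inputs with fewer than 3 genes detected in both.
    """
    ta = pd.Series(
        np.asarray(sp.csr_matrix(bins_a.X).sum(axis=0)).ravel(), index=bins_a.var_names
    )
    tb = pd.Series(
        np.asarray(sp.csr_matrix(bins_b.X).sum(axis=0)).ravel(), index=bins_b.var_names
    )
    union = ta.index.union(tb.index)
    ta = ta.reindex(union, fill_value=0).astype(float)
    tb = tb.reindex(union, fill_value=0).astype(float)
    both_nonzero = int(((ta > 0) & (tb > 0)).sum())
    if both_nonzero < 3:
        raise ValueError("fewer than 3 genes detected in both sections")
    va, vb = (np.log1p(ta), np.log1p(tb)) if log_transform else (ta, tb)
    r, _ = scipy.stats.pearsonr(va, vb)
    return {
        "r": float(r),
        "r2": float(r**2),
        "n_genes": int(len(union)),
        "n_genes_in_both": both_nonzero,
        "log_transform": log_transform,
    }
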