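"""Readers, writers and renderers for the spatial expression formats.

The central on-disk format is the GEM table: a tab-separated file with one
row per (gene, spot) pair carrying the UMI count captured at that spot.
Spot coordinates are 0-based integers in units of the array pitch
(500 nm center-to-center by default), so a coordinate is simultaneously a
chip position and a pixel index when the matrix is rendered as an image.

Segmented-cell expression matrices are exchanged as MatrixMarket triplets
(genes x cells, 1-based indices) next to ``features.tsv`` / ``barcodes.tsv``
/ ``cell_meta.tsv``, the layout most single-cell tooling expects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

DEFAULT_PITCH_NM = 500.0

GEM_COLUMNS = ["geneID", "x", "y", "MIDCount"]

_GENE_ALIASES = {"geneid", "gene", "gene_id"}
_COUNT_ALIASES = {"midcount", "count", "counts", "umicount", "umi_count"}


class GemFormatError(ValueError):
    """Raised when a GEM file violates the dialect contract."""


@dataclass
class SpotMatrix:
    """Sparse (gene, x, y) -> UMI count table on the chip grid.

    ``records`` holds one row per unique (gene, x, y) with a positive
    integer count; ``pitch_nm`` is the physical center-to-center spacing
    of adjacent spots.
    """

    records: pd.DataFrame
    pitch_nm: float = DEFAULT_PITCH_NM

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in GEM_COLUMNS if c not in df.columns]
        if missing:
            raise GemFormatError(f"SpotMatrix records missing columns: {missing}")
        df = df[GEM_COLUMNS].copy()
        if len(df):
            if (df["MIDCount"] < 1).any():
                raise GemFormatError("SpotMatrix counts must be >= 1")
            if (df["x"] < 0).any() or (df["y"] < 0).any():
                raise GemFormatError("SpotMatrix coordinates must be non-negative")
            if df.duplicated(["geneID", "x", "y"]).any():
                raise GemFormatError("duplicate (gene, x, y) records; sum them first")
        df["x"] = df["x"].astype(np.int64)
        df["y"] = df["y"].astype(np.int64)
        df["MIDCount"] = df["MIDCount"].astype(np.int64)
        self.records = df.reset_index(drop=True)

    # -- summaries -------------------------------------------------------
    @property
    def total_umi(self) -> int:
        return int(self.records["MIDCount"].sum())

    @property
    def n_genes(self) -> int:
        return int(self.records["geneID"].nunique())

    @property
    def extent(self) -> tuple[int, int]:
        """(max_x, max_y) over the recorded spots; (-1, -1) when empty."""
        if not len(self.records):
            return (-1, -1)
        return (int(self.records["x"].max()), int(self.records["y"].max()))

    def sorted(self) -> "SpotMatrix":
        df = self.records.sort_values(["geneID", "x", "y"], kind="mergesort")
        return SpotMatrix(df.reset_index(drop=True), self.pitch_nm)

    def equals(self, other: "SpotMatrix") -> bool:
        return self.sorted().records.equals(other.sorted().records)


def _canonical_columns(columns: list[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        low = col.strip().lower()
        if low in _GENE_ALIASES or low == "geneid":
            mapping[col] = "geneID"
        elif low in _COUNT_ALIASES:
            mapping[col] = "MIDCount"
        elif low in {"x", "y"}:
            mapping[col] = low
    return mapping


def read_gem(path: str | Path, pitch_nm: float = DEFAULT_PITCH_NM) -> SpotMatrix:
    """Parse a GEM TSV into a :class:`SpotMatrix`.

    Leading ``#`` comment lines are ignored. Duplicate (gene, x, y) rows are
    summed with a warning; negative counts or coordinates reject the file
    with the offending row number.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df = df.rename(columns=_canonical_columns(list(df.columns)))
    missing = [c for c in GEM_COLUMNS if c not in df.columns]
    if missing:
        raise GemFormatError(f"{path}: missing GEM column(s) {missing}")
    df = df[GEM_COLUMNS]
    for col in ("x", "y", "MIDCount"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise GemFormatError(f"{path}: negative {col} at data row {int(bad[0])}")
    bad = df.index[df["MIDCount"] == 0]
    if len(bad):
        raise GemFormatError(f"{path}: zero count at data row {int(bad[0])}")
    if df.duplicated(["geneID", "x", "y"]).any():
        warnings.warn(f"{path}: duplicate (gene, x, y) rows summed", stacklevel=2)
        df = df.groupby(["geneID", "x", "y"], as_index=False)["MIDCount"].sum()
    return SpotMatrix(df, pitch_nm=pitch_nm)


def write_gem(matrix: SpotMatrix, path: str | Path) -> None:
    """Write a GEM TSV with deterministic (gene, x, y) row order."""
    matrix = matrix.sorted()
    matrix.records.to_csv(path, sep="\t", index=False)


def render_umi_image(
    matrix: SpotMatrix, scale: int = 1, dtype=np.uint16
) -> np.ndarray:
    """Render per-spot total UMI as a grayscale image.

    Pixel ``[y, x]`` holds the summed UMI of spot (x, y), clipped to the
    output bit depth; dimensions are ``(extent + 1) * scale``. An empty
    matrix renders to a 1x1 zero image with a warning.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if not len(matrix.records):
        warnings.warn("rendering empty SpotMatrix as 1x1 zero image", stacklevel=2)
        return np.zeros((scale, scale), dtype=dtype)
    max_x, max_y = matrix.extent
    img = np.zeros((max_y + 1, max_x + 1), dtype=np.int64)
    totals = matrix.records.groupby(["x", "y"])["MIDCount"].sum()
    xs = totals.index.get_level_values("x").to_numpy()
    ys = totals.index.get_level_values("y").to_numpy()
    img[ys, xs] = totals.to_numpy()
    img = np.clip(img, 0, np.iinfo(dtype).max).astype(dtype)
    if scale > 1:
        img = np.repeat(np.repeat(img, scale, axis=0), scale, axis=1)
    return img


# -- segmented-cell matrices ---------------------------------------------

_CELL_META_COLS = ["centroid_x", "centroid_y", "area_px", "n_genes", "n_umi"]


def refresh_cell_metadata(cells: AnnData) -> AnnData:
    """Recompute n_genes / n_umi from the count matrix in place."""
    X = sp.csr_matrix(cells.X)
    cells.obs["n_genes"] = np.asarray((X > 0).sum(axis=1)).ravel()
    cells.obs["n_umi"] = np.asarray(X.sum(axis=1)).ravel().astype(np.int64)
    return cells


def write_cell_matrix(cells: AnnData, out_dir: str | Path) -> None:
    """Write a cells x genes AnnData as MTX (genes x cells) plus TSV sidecars."""
    if cells.n_vars == 0:
        raise ValueError("cell matrix has an empty gene set")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(cells.X.T).astype(np.int64)  # genes x cells, 1-based in file
    scipy.io.mmwrite(out / "matrix.mtx", X, field="integer")
    pd.Series(cells.var_names).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(cells.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    meta_cols = [c for c in _CELL_META_COLS if c in cells.obs.columns]
    cells.obs[meta_cols].to_csv(out / "cell_meta.tsv", sep="\t")


def _read_single_column(path: Path) -> pd.Series:
    try:
        return pd.read_csv(path, sep="\t", header=None)[0].astype(str)
    except pd.errors.EmptyDataError:
        return pd.Series([], dtype=str)


def read_cell_matrix(out_dir: str | Path) -> AnnData:
    out = Path(out_dir)
    X = sp.csr_matrix(scipy.io.mmread(out / "matrix.mtx").T).astype(np.int64)
    genes = _read_single_column(out / "features.tsv")
    barcodes = _read_single_column(out / "barcodes.tsv")
    try:
        obs = pd.read_csv(out / "cell_meta.tsv", sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        obs = pd.DataFrame(index=pd.Index([], dtype=str))
    obs.index = obs.index.astype(str)
    adata = AnnData(X=X, obs=obs.loc[barcodes], var=pd.DataFrame(index=genes))
    adata.obs_names = barcodes
    return adata
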