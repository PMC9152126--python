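"""Ground-truthed simulators for every input the pipeline consumes.

The generators emulate a gridded capture chip (500 nm pitch): a region
layout over the spot grid, region-structured negative-binomial expression
with planted marker genes, coordinate-barcoded reads with injected CID
errors, nuclei-staining images with a known label map, and regulons whose
targets are coupled to a home region. Every generator is a pure function
of its parameters and seed, and every dataset ships with its ground truth
so downstream stages can be scored without peeking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .demux import BarcodeWhitelist, PHRED_OFFSET
from .gem_io import SpotMatrix, DEFAULT_PITCH_NM

_BASES = np.array(list("ACGT"))


@dataclass
class TissueSimSpec:
    """Study conditions for one simulated tissue section.

    Defaults describe the benchmark tissue used throughout: a 100x100 grid
    of spots split into 5 vertical stripes (a cartoon of cortical layering),
    200 genes of which 10 per region are markers elevated 8-fold over a
    negative-binomial baseline with mean 0.5 and size (dispersion) 2.
    """

    grid_width: int = 100
    grid_height: int = 100
    pitch_nm: float = DEFAULT_PITCH_NM
    n_regions: int = 5
    layout_kind: str = "stripes"
    n_genes: int = 200
    markers_per_region: int = 10
    baseline_mean: float = 0.5
    marker_fold: float = 8.0
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_width < 1 or self.grid_height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_regions * self.markers_per_region > self.n_genes:
            raise ValueError("not enough genes for the requested markers")

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"gene{i:0{width}d}" for i in range(self.n_genes)]


@dataclass
class TissueTruth:
    """Ground truth for a simulated section: region per spot and marker map."""

    region: np.ndarray  # (grid_height, grid_width), labels 1..n_regions
    markers: pd.DataFrame  # columns: gene, region

    def region_of_spots(self, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        return self.region[ys, xs]

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        h, w = self.region.shape
        yy, xx = np.mgrid[0:h, 0:w]
        pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "region": self.region.ravel()}
        ).to_csv(prefix.with_suffix(".regions.tsv"), sep="\t", index=False)
        self.markers.to_csv(prefix.with_suffix(".markers.tsv"), sep="\t", index=False)


def generate_region_layout(spec: TissueSimSpec) -> np.ndarray:
    """Partition the spot grid into labelled regions.

    ``stripes`` gives contiguous vertical bands of equal width (remainder
    columns join the last band); ``voronoi`` labels each spot by its
    nearest of ``n_regions`` random seed points (ties to the lower seed).
    """
    h, w, r = spec.grid_height, spec.grid_width, spec.n_regions
    if spec.layout_kind == "stripes":
        if r > w:
            raise ValueError("more stripe regions than grid columns")
        band = w // r
        col_region = np.minimum(np.arange(w) // band, r - 1) + 1
        return np.tile(col_region, (h, 1)).astype(np.int32)
    if spec.layout_kind == "voronoi":
        rng = np.random.default_rng(spec.seed)
        n_spots = h * w
        if r > n_spots:
            raise ValueError("more voronoi regions than spots")
        centers = rng.choice(n_spots, size=r, replace=False)
        cy, cx = np.divmod(centers, w)
        yy, xx = np.mgrid[0:h, 0:w]
        d2 = (
            (xx[..., None] - cx[None, None, :]) ** 2
            + (yy[..., None] - cy[None, None, :]) ** 2
        )
        return (np.argmin(d2, axis=-1) + 1).astype(np.int32)
    raise ValueError(f"unknown layout_kind {spec.layout_kind!r}")


def generate_expression(
    spec: TissueSimSpec, layout: np.ndarray | None = None
) -> tuple[SpotMatrix, TissueTruth]:
    """Draw NB counts per (spot, gene) with planted region markers.

    Marker genes of region r have mean ``baseline_mean * marker_fold``
    inside r and ``baseline_mean`` elsewhere; all other genes sit at the
    baseline everywhere. Counts are NB with size ``dispersion`` so
    var = mean + mean^2 / dispersion. Zero draws are simply absent from
    the returned matrix.
    """
    if layout is None:
        layout = generate_region_layout(spec)
    if layout.shape != (spec.grid_height, spec.grid_width):
        raise ValueError("layout does not cover the spot grid")
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names
    marker_rows = []
    gene_region = np.zeros(spec.n_genes, dtype=np.int32)  # 0 = not a marker
    gi = 0
    for region in range(1, spec.n_regions + 1):
        for _ in range(spec.markers_per_region):
            gene_region[gi] = region
            marker_rows.append((genes[gi], region))
            gi += 1
    markers = pd.DataFrame(marker_rows, columns=["gene", "region"])

    flat_region = layout.ravel()  # spot order: row-major, y then x
    n_spots = flat_region.size
    theta = spec.dispersion
    recs_gene, recs_x, recs_y, recs_c = [], [], [], []
    h, w = layout.shape
    yy, xx = np.mgrid[0:h, 0:w]
    xs_flat, ys_flat = xx.ravel(), yy.ravel()
    for j, gene in enumerate(genes):
        mean = np.full(n_spots, spec.baseline_mean)
        if gene_region[j]:
            mean[flat_region == gene_region[j]] *= spec.marker_fold
        p = theta / (theta + mean)
        counts = rng.negative_binomial(theta, p)
        nz = counts > 0
        if nz.any():
            recs_gene.append(np.full(nz.sum(), gene))
            recs_x.append(xs_flat[nz])
            recs_y.append(ys_flat[nz])
            recs_c.append(counts[nz])
    df = pd.DataFrame(
        {
            "geneID": np.concatenate(recs_gene) if recs_gene else [],
            "x": np.concatenate(recs_x) if recs_x else [],
            "y": np.concatenate(recs_y) if recs_y else [],
            "MIDCount": np.concatenate(recs_c) if recs_c else [],
        }
    )
    return SpotMatrix(df, pitch_nm=spec.pitch_nm), TissueTruth(layout, markers)


# -- whitelist -----------------------------------------------------------


def make_whitelist(grid_width: int, grid_height: int) -> BarcodeWhitelist:
    """Deterministic chip whitelist with pairwise Hamming distance >= 3.

    Spot index is written in base 4 and each digit repeated three times, so
    two distinct CIDs differ in at least one digit, hence >= 3 positions.
    This makes every single-substitution error uniquely correctable.
    """
    n = grid_width * grid_height
    digits = max(1, math.ceil(math.log(max(n, 2), 4)))
    if 4**digits < n:
        digits += 1
    mapping = {}
    for idx in range(n):
        code = []
        v = idx
        for _ in range(digits):
            code.append("ACGT"[v % 4] * 3)
            v //= 4
        seq = "".join(code)
        mapping[seq] = (idx % grid_width, idx // grid_width)
    return BarcodeWhitelist(mapping)


# -- reads ---------------------------------------------------------------


def _int_to_seq(codes: np.ndarray, length: int) -> list[str]:
    out = []
    for c in codes:
        s = []
        for _ in range(length):
            s.append("ACGT"[c % 4])
            c //= 4
        out.append("".join(s))
    return out


def generate_reads(
    spot_matrix: SpotMatrix,
    whitelist: BarcodeWhitelist,
    cid_error_rate: float = 0.0,
    umi_len: int = 10,
    phred_high: int = 30,
    low_qual_prob: float = 0.0,
    low_qual_phred: int = 8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit one read per molecule of ``spot_matrix``, with optional CID errors.

    A fraction ``cid_error_rate`` of reads carries exactly one substitution
    in the CID. UMIs within one (spot, gene) group are drawn with pairwise
    Hamming distance >= 2 so one-mismatch collapsing recovers the exact
    molecule count. Per-base UMI qualities sit at ``phred_high`` with an
    independent ``low_qual_prob`` chance of dropping to ``low_qual_phred``.

    Returns (reads, truth), row-aligned: truth records each read's intended
    spot, gene and UMI.
    """
    if not 0 <= cid_error_rate < 1:
        raise ValueError("cid_error_rate must be in [0, 1)")
    if umi_len < 1:
        raise ValueError("umi_len must be >= 1")
    rng = np.random.default_rng(seed)
    coord_to_cid = {xy: cid for cid, xy in whitelist.mapping.items()}
    spots = set(zip(spot_matrix.records["x"], spot_matrix.records["y"]))
    if not spots <= set(coord_to_cid):
        raise ValueError("whitelist does not cover all spots in the matrix")

    cids, umis, genes_col, tx, ty = [], [], [], [], []
    umi_space = 4**umi_len
    for rec in spot_matrix.records.itertuples():
        k = rec.MIDCount
        # rejection-sample k UMIs with pairwise Hamming >= 2
        chosen: list[str] = []
        while len(chosen) < k:
            cand = _int_to_seq(rng.integers(0, umi_space, size=1), umi_len)[0]
            if all(sum(a != b for a, b in zip(cand, u)) >= 2 for u in chosen):
                chosen.append(cand)
        cid = coord_to_cid[(rec.x, rec.y)]
        for u in chosen:
            cids.append(cid)
            umis.append(u)
            genes_col.append(rec.geneID)
            tx.append(rec.x)
            ty.append(rec.y)

    n_reads = len(cids)
    order = rng.permutation(n_reads)
    cids = [cids[i] for i in order]
    umis = [umis[i] for i in order]
    genes_col = [genes_col[i] for i in order]
    tx = [tx[i] for i in order]
    ty = [ty[i] for i in order]

    mutated = rng.random(n_reads) < cid_error_rate
    cid_len = whitelist.cid_length
    for i in np.flatnonzero(mutated):
        pos = int(rng.integers(cid_len))
        old = cids[i][pos]
        new = rng.choice([b for b in "ACGT" if b != old])
        cids[i] = cids[i][:pos] + new + cids[i][pos + 1 :]

    quals = []
    hi = chr(PHRED_OFFSET + phred_high)
    lo = chr(PHRED_OFFSET + low_qual_phred)
    if low_qual_prob > 0:
        drop = rng.random((n_reads, umi_len)) < low_qual_prob
        for i in range(n_reads):
            quals.append("".join(lo if d else hi for d in drop[i]))
    else:
        quals = [hi * umi_len] * n_reads

    reads = pd.DataFrame(
        {"cid": cids, "umi": umis, "umi_quals": quals, "gene": genes_col}
    )
    reads["mapq"] = pd.array([pd.NA] * n_reads, dtype="Int64")
    truth = pd.DataFrame(
        {
            "x": tx,
            "y": ty,
            "gene": genes_col,
            "umi": umis,
            "cid_mutated": mutated,
        }
    )
    return reads, truth


# -- nuclei imaging ------------------------------------------------------


def generate_nuclei_image(
    n_cells: int,
    image_shape: tuple[int, int] = (512, 512),
    radius_px: float = 20.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    touching_pairs: int = 0,
    foreground: float = 0.6,
    background: float = 0.1,
    margin_px: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render bright nuclei discs over a dark noisy background.

    Non-touching cells keep center distance >= 2*radius + margin;
    ``touching_pairs`` of the cells are instead placed as pairs at center
    distance 1.5*radius to exercise watershed splitting. Returns the
    16-bit image and the true integer label map (0 = background).
    """
    if radius_px <= 0:
        raise ValueError("radius must be positive")
    if touching_pairs * 2 > n_cells:
        raise ValueError("touching_pairs exceeds n_cells")
    h, w = image_shape
    footprint = (2 * radius_px + margin_px) ** 2
    if n_cells * footprint > 0.5 * h * w:
        raise ValueError("n_cells exceeds packable capacity of the image")
    rng = np.random.default_rng(seed)

    centers: list[tuple[float, float]] = []
    min_d = 2 * radius_px + margin_px

    def far_enough(y: float, x: float, exclude: int = 0) -> bool:
        pool = centers if exclude == 0 else centers[:-exclude]
        return all((y - cy) ** 2 + (x - cx) ** 2 >= min_d**2 for cy, cx in pool)

    pad = radius_px + 2
    attempts = 0
    placed_pairs = 0
    while len(centers) < n_cells:
        attempts += 1
        if attempts > 200_000:
            raise ValueError("could not place all cells; image too crowded")
        y = rng.uniform(pad, h - pad)
        x = rng.uniform(pad, w - pad)
        if placed_pairs < touching_pairs:
            ang = rng.uniform(0, 2 * np.pi)
            y2 = y + 1.5 * radius_px * np.sin(ang)
            x2 = x + 1.5 * radius_px * np.cos(ang)
            if not (pad <= y2 <= h - pad and pad <= x2 <= w - pad):
                continue
            if far_enough(y, x) and far_enough(y2, x2):
                centers.append((y, x))
                centers.append((y2, x2))
                placed_pairs += 1
        else:
            if far_enough(y, x):
                centers.append((y, x))

    labels = np.zeros((h, w), dtype=np.int32)
    img = np.full((h, w), background, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    for lab, (cy, cx) in enumerate(centers, start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disc = d2 <= radius_px**2
        img[disc] = foreground
        # touching pairs overlap; later label wins on the overlap ridge
        labels[disc] = lab
    img += rng.normal(0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    img16 = np.round(img * 65535).astype(np.uint16)
    return img16, labels


# -- regulons ------------------------------------------------------------


def generate_regulons(
    truth: TissueTruth,
    gene_universe: list[str],
    n_regulons: int = 5,
    genes_per_regulon: int = 10,
    region_coupling: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, list[str]], pd.Series]:
    """Plant regulons whose targets favour one region's markers.

    Regulon i is assigned home region ``(i % n_regions) + 1``; a fraction
    ``region_coupling`` of its targets are drawn from that region's planted
    markers and the remainder uniformly from the rest of the gene universe.
    Returns (regulon -> targets, regulon -> home region).
    """
    if genes_per_regulon > len(gene_universe):
        raise ValueError("genes_per_regulon exceeds the gene universe")
    if not 0 <= region_coupling <= 1:
        raise ValueError("region_coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    regions = sorted(truth.markers["region"].unique())
    regulons: dict[str, list[str]] = {}
    homes = {}
    for i in range(n_regulons):
        region = regions[i % len(regions)]
        name = f"TF{i:02d}"
        region_markers = truth.markers.loc[
            truth.markers["region"] == region, "gene"
        ].tolist()
        n_coupled = min(round(region_coupling * genes_per_regulon), len(region_markers))
        coupled = list(rng.choice(region_markers, size=n_coupled, replace=False))
        rest_pool = [g for g in gene_universe if g not in coupled]
        n_rest = genes_per_regulon - n_coupled
        rest = list(rng.choice(rest_pool, size=n_rest, replace=False))
        regulons[name] = sorted(coupled + rest)
        homes[name] = region
    return regulons, pd.Series(homes, name="home_region")


def write_regulons(regulons: dict[str, list[str]], path: str | Path) -> None:
    """TSV dialect: regulon name, tab, comma-separated target genes."""
    with open(path, "w") as fh:
        fh.write("regulon\ttargets\n")
        for name in sorted(regulons):
            fh.write(f"{name}\t{','.join(regulons[name])}\n")


def read_regulons(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {r.regulon: r.targets.split(",") for r in df.itertuples()}
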