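"""Coordinate-barcode demultiplexing: reads -> spatial expression matrix.

Each read carries a coordinate identity (CID) barcode naming one spot on
the capture chip, a unique molecular identifier (UMI) with per-base Phred
qualities, and a gene assignment (a direct gene tag on the synthetic path,
or an annotated alignment with a MAPQ on the SAM path). The pipeline:

1. UMI quality filter: drop reads whose UMI contains an N, or more than
   two bases with quality below 10.
2. CID matching against the chip whitelist, allowing one base mismatch;
   a read whose barcode has zero or multiple whitelist entries at Hamming
   distance one stays unassigned (a wrong rescue would misplace the
   molecule).
3. MAPQ filter: drop aligned reads with MAPQ < 10 (tag-only reads pass).
4. Group by (spot, gene) and collapse UMIs allowing one mismatch: the
   molecule count is the number of connected components of the graph
   joining UMI sequences at Hamming distance <= 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gem_io import SpotMatrix, DEFAULT_PITCH_NM

_BASES = "ACGT"

DEFAULT_MIN_MAPQ = 10
DEFAULT_MIN_UMI_QUAL = 10
DEFAULT_MAX_LOW_QUAL_BASES = 2
PHRED_OFFSET = 33


class WhitelistError(ValueError):
    pass


@dataclass
class BarcodeWhitelist:
    """Map from CID sequence to designed chip coordinate (x, y)."""

    mapping: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise WhitelistError("whitelist is empty")
        lengths = {len(s) for s in self.mapping}
        if len(lengths) != 1:
            raise WhitelistError(f"whitelist CIDs have mixed lengths {sorted(lengths)}")
        self.cid_length = lengths.pop()

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, seq: str) -> bool:
        return seq in self.mapping

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BarcodeWhitelist":
        df = pd.read_csv(path, sep="\t", dtype={"cid": str})
        return cls({r.cid: (int(r.x), int(r.y)) for r in df.itertuples()})

    def write_tsv(self, path: str | Path) -> None:
        rows = sorted((x, y, cid) for cid, (x, y) in self.mapping.items())
        df = pd.DataFrame(rows, columns=["x", "y", "cid"])[["cid", "x", "y"]]
        df.to_csv(path, sep="\t", index=False)

    def min_pairwise_distance_lower_bound(self, sample: int = 200, seed: int = 0) -> int:
        """Empirical lower-bound check on pairwise Hamming distance (sampled)."""
        rng = np.random.default_rng(seed)
        seqs = list(self.mapping)
        idx = rng.choice(len(seqs), size=min(sample, len(seqs)), replace=False)
        best = self.cid_length
        for i in idx:
            for j in idx:
                if i < j:
                    d = hamming(seqs[i], seqs[j])
                    best = min(best, d)
        return best


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return sum(c1 != c2 for c1, c2 in zip(a, b))


def _one_mismatch_variants(seq: str):
    for i, orig in enumerate(seq):
        for b in _BASES:
            if b != orig:
                yield seq[:i] + b + seq[i + 1 :]


def match_cid(observed: str, whitelist: BarcodeWhitelist) -> tuple[int, int] | None:
    """Resolve an observed CID to its chip coordinate, allowing one mismatch.

    Exact hits win immediately; otherwise the unique whitelist entry at
    Hamming distance one is returned, and zero or multiple candidates leave
    the read unassigned (``None``). Length mismatches raise ``ValueError``.
    """
    if len(observed) != whitelist.cid_length:
        raise ValueError(
            f"CID length {len(observed)} != whitelist length {whitelist.cid_length}"
        )
    hit = whitelist.mapping.get(observed)
    if hit is not None:
        return hit
    found: tuple[int, int] | None = None
    for variant in _one_mismatch_variants(observed):
        coord = whitelist.mapping.get(variant)
        if coord is not None:
            if found is not None and coord != found:
                return None  # ambiguous rescue
            if found is not None:
                continue
            found = coord
    return found


def filter_umi(
    umi_seq: str,
    umi_quals: np.ndarray | list[int],
    min_qual: int = DEFAULT_MIN_UMI_QUAL,
    max_low: int = DEFAULT_MAX_LOW_QUAL_BASES,
) -> bool:
    """Keep a UMI unless it contains an N or more than two bases under Q10."""
    if len(umi_quals) != len(umi_seq):
        raise ValueError("UMI sequence/quality length mismatch")
    if "N" in umi_seq:
        return False
    low = sum(1 for q in umi_quals if q < min_qual)
    return low <= max_low


def filter_mapq(mapq: int | None, min_mapq: int = DEFAULT_MIN_MAPQ) -> bool:
    """Keep reads with MAPQ >= threshold; tag-only reads (no MAPQ) pass."""
    if mapq is None:
        return True
    return mapq >= min_mapq


def collapse_umis(umis) -> int:
    """Count distinct molecules among the UMIs of one (spot, gene) group.

    Builds the graph whose nodes are distinct UMI sequences and whose edges
    join pairs at Hamming distance <= 1, and returns its number of connected
    components. Mixed lengths reject the group.
    """
    distinct = sorted(set(umis))
    if not distinct:
        return 0
    if len({len(u) for u in distinct}) != 1:
        raise ValueError("UMIs of mixed length in one group")
    index = {u: i for i, u in enumerate(distinct)}
    parent = list(range(len(distinct)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for u, i in index.items():
        for v in _one_mismatch_variants(u):
            j = index.get(v)
            if j is not None:
                union(i, j)
    return len({find(i) for i in range(len(distinct))})


# -- pipeline ------------------------------------------------------------


@dataclass
class DemuxReport:
    """Per-reason read accounting; reads_in = assigned + all rejections."""

    reads_in: int = 0
    rejected_umi: int = 0
    rejected_cid_length: int = 0
    unassigned_cid: int = 0
    rejected_mapq: int = 0
    rejected_no_gene: int = 0
    reads_assigned: int = 0
    filter_order: tuple[str, ...] = ("filter_umi", "match_cid", "filter_mapq")

    def check_accounting(self) -> bool:
        return self.reads_in == (
            self.reads_assigned
            + self.rejected_umi
            + self.rejected_cid_length
            + self.unassigned_cid
            + self.rejected_mapq
            + self.rejected_no_gene
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def _decode_quals(qual_string: str) -> np.ndarray:
    return np.frombuffer(qual_string.encode("ascii"), dtype=np.uint8) - PHRED_OFFSET


def demultiplex(
    reads: pd.DataFrame,
    whitelist: BarcodeWhitelist,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[pd.DataFrame, DemuxReport]:
    """Assign each read to a spot, keeping per-read provenance.

    ``reads`` columns: cid, umi, umi_quals (Phred+33 string), gene
    (may be null), mapq (nullable). Returns the surviving reads with x, y
    columns plus the rejection report; row order follows the input.
    """
    report = DemuxReport(reads_in=len(reads))
    low_cut = chr(PHRED_OFFSET + DEFAULT_MIN_UMI_QUAL)

    kept_rows = []
    xs: list[int] = []
    ys: list[int] = []
    cid_len = whitelist.cid_length
    has_mapq = "mapq" in reads.columns
    for row in reads.itertuples():
        umi = row.umi
        if "N" in umi or sum(c < low_cut for c in row.umi_quals) > 2:
            report.rejected_umi += 1
            continue
        cid = row.cid
        if len(cid) != cid_len:
            report.rejected_cid_length += 1
            continue
        coord = match_cid(cid, whitelist)
        if coord is None:
            report.unassigned_cid += 1
            continue
        mapq = getattr(row, "mapq", None) if has_mapq else None
        if mapq is not None and not pd.isna(mapq) and mapq < min_mapq:
            report.rejected_mapq += 1
            continue
        if row.gene is None or (isinstance(row.gene, float) and np.isnan(row.gene)):
            report.rejected_no_gene += 1
            continue
        kept_rows.append(row.Index)
        xs.append(coord[0])
        ys.append(coord[1])
    assigned = reads.loc[kept_rows, ["umi", "gene"]].copy()
    assigned["x"] = xs
    assigned["y"] = ys
    report.reads_assigned = len(assigned)
    assert report.check_accounting()
    return assigned, report


def build_spot_matrix(
    reads: pd.DataFrame,
    whitelist: BarcodeWhitelist,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    pitch_nm: float = DEFAULT_PITCH_NM,
) -> tuple[SpotMatrix, DemuxReport]:
    """Full demultiplexing pipeline: reads -> SpotMatrix + report.

    Order: UMI quality filter, CID matching (one mismatch), MAPQ filter,
    then per-(spot, gene) UMI collapapsing at Hamming <= 1; the resulting
    count is the number of distinct molecules.
    """
    assigned, report = demultiplex(reads, whitelist, min_mapq=min_mapq)
    records = []
    if len(assigned):
        for (x, y, gene), group in assigned.groupby(["x", "y", "gene"], sort=True):
            records.append((gene, x, y, collapse_umis(group["umi"].tolist())))
    df = pd.DataFrame(records, columns=["geneID", "x", "y", "MIDCount"])
    if len(df):
        df = df[df["MIDCount"] > 0]
    return SpotMatrix(df, pitch_nm=pitch_nm), report


# -- I/O dialects --------------------------------------------------------


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    """Read the synthetic TSV read dialect (cid, umi, umi_quals, gene, mapq)."""
    df = pd.read_csv(
        path, sep="\t", dtype={"cid": str, "umi": str, "umi_quals": str, "gene": str}
    )
    if "mapq" not in df.columns:
        df["mapq"] = pd.NA
    df["mapq"] = pd.array(df["mapq"], dtype="Int64")
    return df


def write_reads_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_reads_sam(
    path: str | Path,
    gene_tag: str = "GE",
    cid_tag: str = "CB",
    umi_tag: str = "UB",
    umi_qual_tag: str = "UY",
    default_umi_qual: int = 30,
) -> pd.DataFrame:
    """Load gene-annotated alignments (SAM) into the read table dialect.

    The CID and UMI ride in tags; records without the gene tag keep a null
    gene (rejected downstream), and a missing UMI-quality tag is filled
    with a constant high quality.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if not rec.has_tag(cid_tag) or not rec.has_tag(umi_tag):
                continue
            umi = rec.get_tag(umi_tag)
            quals = (
                rec.get_tag(umi_qual_tag)
                if rec.has_tag(umi_qual_tag)
                else chr(PHRED_OFFSET + default_umi_qual) * len(umi)
            )
            gene = rec.get_tag(gene_tag) if rec.has_tag(gene_tag) else None
            rows.append(
                (rec.get_tag(cid_tag), umi, quals, gene, rec.mapping_quality)
            )
    df = pd.DataFrame(rows, columns=["cid", "umi", "umi_quals", "gene", "mapq"])
    df["mapq"] = pd.array(df["mapq"], dtype="Int64")
    return df
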