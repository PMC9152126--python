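# stereopipe

A tested, reusable pipeline for spatial transcriptomics on DNB-gridded
capture chips (Stereo-seq-style data), from coordinate-barcoded reads to
biology-ready matrices:

1. **Read demultiplexing** — coordinate-identity (CID) barcode matching
   against the chip whitelist with one-mismatch correction, UMI quality
   filtering, MAPQ filtering, and one-mismatch UMI collapsing into a
   spatial gene × (x, y) expression matrix (GEM).
2. **Binning** — aggregation of 500 nm-pitch spots into square bins
   (bin 50 = 25 µm), per-bin QC, and replicate comparison via per-gene
   pseudobulk correlation.
3. **Spatially constrained clustering** — log-normalization, HVG
   selection, 30-component PCA, a k-NN graph in expression space fused
   with a k-NN graph on bin centroids, Leiden community detection, and
   one-vs-rest Wilcoxon marker calling with a strict DEG rule
   (FC > 2, BH-adjusted p < 0.05, Δpct > 0.1).
4. **Cell segmentation** — adaptive-threshold + Euclidean-distance-seeded
   watershed on a nuclei staining image (block 41, offset 0.003, seed
   distance 15 px), affine registration to the chip grid, per-cell UMI
   aggregation, and cell QC (≥ 300 genes, top 0.2 % removed).
5. **Regulon scoring** — AUCell-style rank-based activity per bin and the
   region-enrichment statistic E(region, regulon) =
   mean activity in region − mean activity over all bins, with a 0.1
   retention floor.

Every stage has a ground-truthed simulator (`stereopipe.simulate`), so the
whole pipeline is testable without any sequencing data: stripe- or
Voronoi-structured negative-binomial tissue with planted marker genes,
reads with injected barcode errors, nuclei images with known label maps,
and regulons coupled to a home region.

## Who this is for

Developers and analysts working with sub-micron gridded spatial
transcriptomics who need a transparent, fully specified reference
implementation of the standard processing chain — each rule (filter
boundaries, collapse semantics, enrichment definitions) is an explicit,
unit-tested contract rather than a black box.

## The statistics at the core

- **UMI collapse count**: the number of distinct molecules at one
  (spot, gene) is the number of connected components of the graph whose
  nodes are distinct UMI sequences and whose edges join pairs at Hamming
  distance ≤ 1 (verified against a brute-force union-find oracle).
- **Spatially constrained clustering**: Leiden (RB-modularity) on
  A = α·A_spatial + (1−α)·A_expression, the weighted union of the two
  symmetrized k-NN graphs (α = 0.5, k_spatial = 6, k_expr = 15).
- **AUCell activity**: with window W = ⌈0.05·n_genes⌉ and k targets at
  0-based ranks p, AUC = Σ_{p<W} (W−p) / (min(k, W)·W) ∈ [0, 1];
  rank-based, hence invariant under monotone transforms of expression.
- **Region enrichment**: E(r, regulon) = mean_r(AUC) − mean_all(AUC);
  the bin-count-weighted mean of E over regions is identically 0.

## Worked example

```python
import stereopipe as spp
from stereopipe.binning import bin_spots

spec = spp.TissueSimSpec(seed=0)            # 100x100 spots, 5 stripes, fold 8
tissue, truth = spp.generate_expression(spec)
wl = spp.make_whitelist(100, 100)           # pairwise Hamming >= 3
reads, _ = spp.generate_reads(tissue, wl, cid_error_rate=0.1, seed=0)
rebuilt, report = spp.build_spot_matrix(reads, wl)
print(rebuilt.equals(tissue), report.reads_assigned)

bins = bin_spots(tissue, 1)
res = spp.spatially_constrained_clustering(bins, n_clusters=5, seed=0)
print(res["partition_fused"].n_clusters)
```

prints `True 1349991` (every molecule of the 1,349,991 simulated UMIs is
recovered to its spot despite 10 % barcode errors, because the whitelist
has pairwise Hamming distance ≥ 3) and `5` (the five stripe regions are
found; their agreement with truth is ARI ≈ 0.997).

The same flow as a narrated analysis lives in `analysis/01…06`:

```sh
python analysis/01_simulate_tissue.py     # data -> scratch/sim/
python analysis/02_demultiplex_reads.py   # -> results/demux_report.json
python analysis/03_bin_and_qc.py
python analysis/04_cluster_regions.py
python analysis/05_segment_cells.py
python analysis/06_regulon_enrichment.py
```

Each step prints what it found and writes a small summary table under
`results/`.

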