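# Methods

This note documents the models, parameter choices, and numerical
conventions behind `stereopipe`, and what the synthetic benchmarks do and
do not demonstrate about real chip data.

## The data model

The capture chip is a rectangular grid of spots at 500 nm
center-to-center pitch (`pitch_nm`, configurable). Spot coordinates are
0-based integers in pitch units, so a spot is simultaneously a chip
position, a GEM table row key, and a pixel index when the matrix is
rendered as an image. The GEM dialect is tab-separated with columns
`geneID`, `x`, `y`, `MIDCount`; duplicate (gene, x, y) rows on input are
summed with a warning (the permissive choice), output rows are sorted by
(gene, x, y) so files diff cleanly. Segmented-cell matrices are written
as MatrixMarket triplets (genes × cells, 1-based) with
`features.tsv` / `barcodes.tsv` / `cell_meta.tsv` sidecars.

## Read processing

Reads carry a CID barcode, a UMI with per-base Phred qualities, and a
gene assignment — either a direct gene tag (synthetic path) or a
gene-annotated alignment with a MAPQ (SAM path; tags `CB`/`UB`/`GE`,
optional `UY` for UMI qualities). The pipeline order is:

1. **UMI quality filter** — reject if the UMI contains an N or more than
   two bases with quality < 10 (both boundaries strict: exactly two low
   bases pass, Q10 itself is not "lower than 10").
2. **CID matching** — exact whitelist hit, else the unique entry at
   Hamming distance 1; zero or multiple candidates leave the read
   unassigned. Ambiguous rescues are rejected rather than resolved by
   abundance because a wrong rescue misplaces a molecule in space.
3. **MAPQ filter** — reject MAPQ < 10; tag-only reads pass.
4. **UMI collapsing** — per (spot, gene), the molecule count is the
   number of connected components of the graph joining distinct UMIs at
   Hamming distance ≤ 1. The component rule is simpler than
   count-weighted directional collapsing and is the documented contract;
   it is verified against a brute-force union-find oracle in the tests.

The filter order (UMI → CID → MAPQ) is a convention recorded in every
`DemuxReport`, which also carries per-reason rejection counts satisfying
`reads_in = assigned + Σ rejections` exactly.

A caveat on monotonicity: adding reads (e.g. by lowering the MAPQ
threshold) can in principle *merge* two UMI components via a bridging
UMI, so spot counts are not monotone in the threshold for arbitrary
input. For reads from the package's generator — which draws within-group
UMIs at pairwise distance ≥ 2 — counts are monotone, and the property
test runs on such reads.

## Binning and replicate QC

Bins are half-open floor-division squares anchored at the grid origin:
spot (x, y) joins bin (⌊x/N⌋, ⌊y/N⌋). Binning is exactly UMI-conserving
for any N and composes: re-binning bin-a output by b equals binning the
source at a·b. Bin 50 at 500 nm pitch spans 25 µm.

Replicate agreement is the Pearson correlation of per-gene pseudobulk
(total UMI per gene over the union gene universe, missing = 0), computed
on log1p totals by default (raw totals via a flag). Whether published
replicate correlations of this kind are per-gene or per-bin is generally
ambiguous; per-gene pseudobulk is this package's documented default.

## Spatially constrained clustering

- **Normalization**: `lognorm` is log1p(count/total·10⁴).
  `pearson_residual` implements analytic Pearson residuals
  (x−μ)/√(μ+μ²/θ) with per-gene μ proportional to the row total, fixed
  θ = 100, clipped at ±√n — a fully specified variance stabilizer with
  the same intent as regularized NB regression. Zero-total rows are
  dropped with a warning.
- **HVG selection** ranks genes by var/mean dispersion of the *de-logged*
  normalized values; on the log scale high-mean genes are compressed and
  genuine between-region variability would rank below shot noise. Ties
  break lexicographically by gene id.
- **PCA**: centered, 30 components by default, full SVD, each component
  sign-fixed so its largest-magnitude loading is positive; degenerate
  rank truncates with a warning.
- **Graphs**: exact k-NN symmetrized by union with binary weights;
  k = 15 in expression space (Euclidean on the embedding), k = 6 on bin
  centroids. Neighbor ties break by node index. The fused graph is the
  weighted union α·A_spatial + (1−α)·A_expression with α = 0.5 — the
  minimal symmetric way to "collapse" two k-NN graphs; α is exposed.
- **Leiden**: RB-modularity objective, mandatory seed, two iterations.
  The resolution for region-level clustering is a free parameter;
  `leiden_target_clusters` finds, by geometric bisection over
  resolutions, a partition with a requested number of communities. The
  benchmark analyses request the number of simulated regions — an
  experimental-design input (like choosing a resolution that yields
  anatomically sensible regions), not a use of per-spot truth labels.
- **Markers/DEGs**: one-vs-rest Wilcoxon rank-sum (asymptotic, two-sided)
  on log-normalized values for genes with max(pct_in, pct_out) ≥ 0.05,
  BH adjustment within each cluster's family, log2FC of de-logged means
  with pseudocount 1e-9. The DEG rule keeps rows with FC > 2 and
  adjusted p < 0.05 and (pct_in − pct_out) > 0.1, all strict.

## Cell segmentation

Images are rescaled to [0, 1] (integer images divide by their dtype
max). Foreground is `pixel > local_mean(block 41) − 0.003`; the offset
is defined on the [0, 1] intensity scale, since an absolute offset is
meaningless without fixing the scale. Seeds are connected components of the Euclidean
distance transform at ≥ 15 px ("distance 15 from the background" read as
the standard distance-seeded watershed recipe), and watershed runs on the
negated distance map restricted to the mask — fully deterministic.

Manual image-to-chip alignment is replaced by a least-squares affine fit
to ≥ 3 non-collinear control-point pairs (identity default for
pre-aligned synthetic data); the RMS residual is reported. Each spot maps
through the inverse transform to a pixel; spots on label L contribute
their full counts to cell L, and assigned + unassigned UMI equals the
source total exactly.

Cell QC drops cells with < 300 detected genes (300 itself passes), then
removes the ⌈0.002·n⌉ top-ranked cells as a doublet proxy — by gene
count per the default reading of "total number of detected genes",
UMI count via a flag. The removal is phrased as a target size so
re-application against the same reference n is a no-op; ties break by
cell id. Segmentation quality is scored by greedy IoU matching at 0.5
with recall/precision/mean-IoU, invariant to label renumbering.

## Regulon activity and enrichment

Genes are ranked per bin by expression descending with ties broken by
fixed gene (column) order, making the AUC deterministic. With window
W = ⌈top_fraction·n_genes⌉ (top_fraction = 0.05, the conventional
default) and targets at 0-based ranks p, AUC = Σ_{p<W}(W−p)/(min(k,W)·W):
all targets at the very top give 1−(k−1)/(2W), none in the window gives 0.
The implementation must match a brute-force recovery-curve integration to
1e-12; that oracle is the contract. Enrichment is the unweighted region
mean minus the global mean; regulons below 0.1 everywhere are dropped.
GRN inference (coexpression + motif pruning) is out of scope — regulons
arrive as files.

## The synthetic tissue and what it shows

The generator's defaults define the benchmark study conditions: a
100×100 spot grid in 5 contiguous vertical stripes (a cartoon of
cortical layering; Voronoi layouts for irregular-region stress tests),
200 genes with 10 markers per region, negative-binomial counts with
baseline mean 0.5 per spot per gene, dispersion (size) θ = 2
(var = μ + μ²/θ), and markers elevated 8-fold in their home region.
Reads default to Phred 30 with a configurable chance of sub-Q10 bases so
the quality filter is exercised; the chip whitelist encodes the spot
index in base 4 with each digit tripled, giving pairwise Hamming
distance ≥ 3 so every single-substitution error is uniquely correctable.
Within one (spot, gene) group, UMIs are drawn at pairwise distance ≥ 2
so one-mismatch collapsing recovers the exact molecule count and
demultiplexing is the exact inverse of read generation.

Nuclei images render uniform-intensity discs (foreground 0.6,
background 0.1) with additive Gaussian noise, sd 0.02 — an SNR of ~25,
typical of nuclear staining; larger noise makes near-zero-offset adaptive
thresholding speckle the background enough to bridge the watershed waist
between touching nuclei. Touching pairs sit at 1.5× radius so the
distance map has two maxima ≥ 15 px separated by a sub-15 px waist.

These simulations validate the *machinery* — inverse-pair correctness,
conservation, oracle agreement, recovery under planted structure. They do
not model mouse-brain anatomy, transcript diffusion/lateral spread,
optical point-spread, segmentation of textured or overlapping 3-D nuclei,
or library-level artifacts (PCR chimeras, index hopping), so passing
benchmarks bound algorithmic behaviour, not performance on real sections.
Problem sizes in the shipped analyses (10⁴ bins, ~1.5×10⁵ reads for the
demultiplexing study, 200 nuclei) are chosen as desk-scale studies with
enough power for the planted effects.

## Known limitations

- One-mismatch CID rescue is exhaustive over 3L variants; fine for
  desk-scale whitelists, but a production chip (10⁸ spots) would want a
  neighborhood-indexed store.
- `normalize` densifies its input; matrices beyond ~10⁵ × 10⁴ would need
  a sparse path.
- The expression k-NN uses exact search (brute force below 4097 nodes,
  tree-based above); approximate neighbors would be needed at
  whole-section scale.
- Wilcoxon p-values use the tie-corrected normal approximation
  throughout; exact small-sample p-values are not implemented.
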