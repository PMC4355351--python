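# Methods

Conventions and algorithmic choices, stage by stage. All genomic coordinates
are 1-based inclusive (GFF3 convention); conversion to 0-based half-open
happens only when writing BED.

## TAR calling and classification

A locus is a transcriptionally active region (TAR) iff FPKM exceeds the
floor (default 0, i.e. strictly positive) in at least one of the 15
organ:stage conditions. TARs over annotated genes inherit the gene category
(`gene_full` vs `gene_pseudo`); expressed loci matching a known intergenic
interval are NTRs (strand `.`). Matrix rows that are neither annotated
genes nor known NTR intervals are a hard error, as are NTR intervals that
overlap an annotated gene span.

**lincRNA filters** (conjunctive, on NTRs): length strictly greater than
200 nt; longest ORF at most 300 amino acids (an ORF of exactly 300 passes);
no protein similarity. The longest ORF scans all six frames from ATG to the
first in-frame stop; the reported length counts the initiator Met and
excludes the stop codon (`ATGAAATAG` → 2). NTRs without a sequence are
reported `uncallable`, never silently dropped.

**cis-NATs**: an expressed gene is a cis-NAT producer iff the summed
opposite-strand overlap from the stranded antisense table reaches the
threshold (default 1 bp). Antisense transcription over non-expressed genes
never produces a call.

## Alternative-splicing event typing

Isoforms are compared pairwise as exon chains; events are deduplicated by
(type, coordinates) across all pairs of a gene.

- **IR** — an intron of one isoform lies entirely within a single exon of
  the other; coordinates are the retained intron.
- **ES** — an internal exon of one isoform lies within a single intron of
  the other *and* the flanking exons share their inner boundaries;
  coordinates are the skipped exon.
- **A5SS / A3SS** — two overlapping exons share exactly one boundary and
  differ at the other. The donor side is the exon end on `+` and the exon
  start on `-` (types swap with strand). The exon across the
  differing-side intron must share its inner boundary in both isoforms —
  this prevents an intron-retention pair from also matching an alternative
  splice site. Coordinates are the differential segment. A change at an
  outermost endpoint (TSS/TES) is never an event, but a splice-site-side
  change of a first/last exon is.
- **MXE** — exons *x* (only in isoform A) and *y* (only in B),
  non-overlapping, each the sole exon between the same shared flanking exon
  pair; coordinates are the sorted exon pair.
- **complex** — a pair whose internal structure differs without matching
  any canonical pattern yields one `complex` event spanning the pair.
  Complex events are excluded from the five-type proportion denominator.

The synthetic generator injects events by modifying the primary transcript
at intron "slots" spaced three introns apart (one event per extra isoform).
The spacing guarantees that events never interact across isoform pairs, so
the classifier must recover the injected (type, coordinates) multiset
exactly — the oracle used throughout the tests.

## Expression profiles and structure coupling

Breadth is the number of conditions with FPKM > 0 (scale-invariant by
construction). The mean expression level averages FPKM over expressed
conditions only. Level classes: low < 5, medium in [5, 200), high ≥ 200
FPKM. For the structure analysis, expressed genes are ranked by mean level
and split into 30 contiguous equal-size bins (ties broken by locus id);
structural features are computed on the primary (longest) isoform. The
inflexion detector takes the argmax of a 3-bin moving average
(edge-padded) and flags boundary maxima as monotone. The interquartile
outlier screen reports linear-interpolation (type-7) quartiles, the spread
statistic (Q3 − Q1) × 3 / Q3, and the conventional fence
Q3 + 3 × (Q3 − Q1).

## Chromosome partitioning

Feature density per Mb is counted by midpoints in half-open sliding windows
(default 10 Mb window, 1 Mb step); Z-scores use the sample (n − 1) SD.
Region membership (R1/R2a/C/R2b/R3) is half-open `[start, end)` with the
last region right-closed.

Changepoints come from binary segmentation under a Gaussian mean-change
model: the best split of a segment is accepted iff the residual
sum-of-squares gain divided by the noise variance exceeds the BIC-style
penalty β = 2 ln n. The noise variance is estimated once as
var(first differences) / 2. Segmentation runs on a **non-overlapping**
(window = step) track: sliding windows share most of their data, which
deflates the first-difference noise estimate and causes gross
oversegmentation (77 spurious changepoints at full scale versus 4 correct
ones on the tiled track). Changepoint positions are reported as the right
edge (bp) of the last window of each left segment.

Region contrasts use Welch's t-test (regions with fewer than 2 observations
are skipped); the density gradient is the Spearman rank correlation between
window density and distance to the centromeric region's midpoint; the
expressed-vs-predicted distribution comparison is a chi-square
goodness-of-fit over windows with the expected counts rescaled to the
observed total.

## Co-expression, insulae, enrichment

The similarity cut is the two-sided critical Pearson correlation at
α = 0.01 for n paired observations, r = t / √(t² + n − 2) with t the
0.995 Student-t quantile at n − 2 df; for n = 15 this is 0.641. Profiles
are clustered by complete linkage on the distance 1 − Pearson and the tree
is cut at distance 1 − r. Zero-variance profiles have undefined
correlation and are placed in the reserved cluster 0. Loci are sorted by id
before clustering and clusters relabelled by first appearance, making the
assignment order-invariant and deterministic.

Insulae are maximal runs of ≥ 2 consecutive genes with intergenic distance
(next start − previous end − 1) at or below 30 kb; overlapping genes count
as distance 0. Adjacent insula members sharing a cluster are co-expressed
neighbor pairs, annotated with orientation (divergent `-/+`, convergent
`+/-`, tandem otherwise) and an optional duplication flag. The headline
percentage counts distinct genes involved in co-expressed pairs over all
insula genes (chains of k genes contribute k, not 2(k−1)).

Per-cluster regional composition is a chi-square test of the cluster's
share across the five regions (2 × regions contingency, df = regions − 1),
flagged unreliable when more than 20% of expected counts fall below 1.
Term enrichment uses the two-sided Fisher exact test with
Benjamini–Hochberg adjustment across terms; degenerate tables with both
off-diagonal margins empty report an odds ratio of 1.

## Synthetic chromosome generator

The generator emulates a 774.4 Mb chromosome (five regions, configurable
per-region gene densities with a telomere-high/centromere-low gradient),
pseudogene and NTR loci, antisense transcription for a configured fraction
of expressed genes (plus decoys over non-expressed genes), and an FPKM
matrix built from eight cluster templates with near-disjoint condition
supports (one constitutive ramp, five organ-specific, one late-stage, one
single-condition). Gene structure couples to expression through a
bell-shaped factor over the expression-rank distribution (peak near rank
21.5/30) and a negative breadth–size term, reproducing the non-monotonic
structure-vs-expression relationship and the size/breadth anticorrelation.
Intergenic gaps follow a small/large mixture around the 30 kb insula scale.
Every locus and injected AS event carries a truth record; output is
deterministic for a fixed seed. `SyntheticConfig.test_scale()` shrinks the
map to ~50 Mb (~480 genes) for fast tests; the defaults produce ~7,480
genes for full-scale recovery runs.
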