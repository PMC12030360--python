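# Methods

## Detection model

A base's score is the capped length of the homopolymer run it belongs to:
`+min(k, run_cap)` inside a run of `k` guanines, `-min(k, run_cap)` inside a
run of `k` cytosines, 0 for A/T/N. The cap (default 4) reflects that a
G-tetrad core needs tracts of about four guanines; longer runs do not make a
window proportionally more quadruplex-prone. N scores 0 and breaks runs.
Soft-masked (lowercase) bases are scanned normally; `skip_masked=True`
treats them as N instead.

Detection averages the scores over a sliding window (`window`, default 25 bp)
and selects windows with mean ≥ `threshold` (default 1.2) or ≤ −threshold,
by sign. The comparison is **inclusive**: a window at exactly the threshold
counts, a deterministic boundary that makes counts reproducible. Selected
same-sign windows that overlap or are exactly adjacent merge into one
candidate. Each candidate is then refined: each end is extended to include
any complete G run (positive sign) or C run (negative sign) crossing the
boundary, then terminal zero-scoring bases are trimmed. The reported score
is the mean base score over the refined interval — it may differ from the
window means that seeded the hit, whose extreme value is kept in a secondary
column (`max_window_mean`). Positive hits carry strand `+` (G-tract on the
forward strand), negative hits strand `-`.

Two cleaning steps, both on by default and both toggleable (`drop_n`,
`dedupe`): hits whose sequence contains N are dropped, and identical
refined intervals are collapsed. Raw detector output can legitimately
contain both.

The scoring rule is antisymmetric under reverse complementation
(`scores(revcomp(s)) = reverse(-scores(s))`), and every downstream rule
(inclusive two-sided threshold, same-sign merging, run extension, zero
trimming) preserves that symmetry, so detection on the reverse complement
yields mirrored intervals with flipped strands and negated scores. The test
suite asserts this on fuzzed sequences and checks the full detector against
a naive re-scan that recomputes every window mean directly.

## Coordinates and regions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on ingest and BED/bedGraph are written 0-based half-open.
Genes without a strand are rejected with a warning. Per gene:

- `promoterN` (N ∈ {2000, 1500, 1000, 500}) is the N bp immediately
  upstream of the gene start in the gene's own orientation — upstream of
  the TSS, not genomic-left — clipped to the contig. A promoter clipped to
  zero length is excluded from spans and logged.
- `TSS500` is 250 bp on each side of the transcription start base (the
  first base of the gene feature, strand-aware); the TSS base itself sits
  in the downstream half. For a `+` gene at `[gs, ge)` this is
  `[gs-250, gs+250)`, for a `-` gene `[ge-250, ge+250)`.
- exon/CDS/UTR are unions over the gene's transcripts; introns are each
  transcript's span minus its exons, unioned per gene. Promoter/TSS regions
  are gene-level, not per-isoform, because all reported statistics are
  per-gene.

A hit counts in a region when they overlap by ≥ 1 bp; one hit may count in
several classes and several genes. Genome-level class densities divide
distinct hits overlapping the class's **interval union** by the union's
span (overlapping promoters are not double-counted); per-gene burdens use
each gene's own region. Both conventions are emitted, since summed per-gene
counts can exceed the union count by construction.

Strand context: a hit whose G-rich strand equals the host gene's strand is
`coding` (the G-tract lies on the sense strand), otherwise `template`;
`double` is the union. Coding and template spans are identical, so density
folds equal count folds.

## Statistics

- Density = `count × 1000 / span_bp`, full precision internally, 2 dp in
  reports. Zero spans give flagged NaN records rather than errors.
- G4SDF (strand difference fold) = `max(cd, td) / min(cd, td)` with the
  dominant side recorded; one-sided-zero gives an infinite, flagged fold,
  both-zero a flagged NaN.
- The significance test for strand differences is an exact two-sided
  binomial on (coding count, template count) with p = 1/2 — the two strand
  contexts of a region class have equal exposure by construction, so under
  no bias each hit is a fair coin. A label-permutation test would measure
  the same thing; the exact binomial was chosen because the counts are the
  sufficient statistic and the null is fully specified.
- DEG filtering: up iff `log2FC ≥ +1` and `padj ≤ 0.05`, down iff
  `log2FC ≤ -1` and `padj ≤ 0.05`, else ns; missing padj is ns. DESeq2
  result tables are consumed as-is (the package does not re-estimate
  dispersions). The strand-fold selection (`fold > 3`, strict) is per-gene
  by default; genes with one strand zero are selected and flagged as
  infinite-fold, genes with zero on both strands are excluded. A pooled
  variant (fold computed on group-summed counts) is available as a flag
  because group-level reporting is ambiguous between the two readings.
- Gene classification bins every annotated gene (zero-count genes
  included) into {0, 1..cutoff, >cutoff} with strict `>` at the cutoff
  (defaults 10 for promoter2000, 5 for TSS500); proportions are over the
  full gene universe.
- Chromosome correlations are Pearson r with two-sided p, requiring ≥ 3
  chromosomes; zero-variance features give flagged NaN records.
- Windowed tracks assign a hit to the window containing its start
  coordinate, so tiling windows conserve the total count exactly.

## Synthetic data

The generator emulates the statistical structure the pipeline is meant to
measure, not real sequence composition:

- Background bases are drawn i.i.d. at 35% GC, then every G/C run of
  length ≥ 3 is broken by rewriting its third base to A/T. With a 25 bp
  window and threshold 1.2, background windows essentially never reach the
  threshold; generation additionally verifies by scanning each chromosome
  and refuses to emit a dataset with any non-planted hit.
- The default planted motif is the telomeric 25-mer
  `GGGTTAGGGTTAGGGTTAGGGTTAG` (mean score 1.48), guaranteed detectable at
  default parameters. Each planted copy is isolated by `window−1` A/T bases
  on both sides, so refinement lands exactly on the planted coordinates —
  ground truth is exact, not statistical. Motif copies are spaced ≥
  window+10 bp apart so none merge.
- Genes (default 40 per 300 kb chromosome, 3 kb long, random strand) sit in
  disjoint slots with their full ±2 kb footprint inside the slot, so genes
  never overlap and coding+template always partitions the double count.
  Each gene has one transcript with two exons, one intron and terminal UTRs.
- Planting zones per gene: the TSS window, the promoter upstream of it, and
  the gene body. Default densities are per kbp by strand context: TSS
  0.5/0.5 (near-equal strands), promoter 0.36/0.18 coding-dominant, gene
  body 0.6125/0.25 — a 2.45:1 coding:template ratio. Counts follow a
  largest-remainder quota across genes so genome totals track the requested
  densities despite small zones.
- DEG structure: 30 upregulated genes get 4 TSS motifs at 3:1
  template:coding, 30 downregulated at 3:1 coding:template (≥ 100 planted
  hits per group, fold exactly 3); the DEG table satisfies the direction
  thresholds exactly, with ns genes mixing small-effect, large-effect-high-p
  and missing-padj rows. Five genes get 12 promoter motifs and five get 6
  TSS motifs to plant known above-cutoff classification counts.
- `perturb` mutates the central G (or C on minus-strand copies) of a chosen
  fraction of motifs to T (A), lowering refined scores; the hit count is
  non-increasing in the fraction.

What the fixture does **not** emulate: real base composition and repeat
structure, overlapping genes and isoform diversity, N gaps, G4 motifs of
heterogeneous strength, and realistic DEG fractions (half the fixture's
genes are DEGs so that group statistics are stable at desk scale; a real
genome has far fewer). Passing recovery tests therefore demonstrates the
correctness of the measurement chain, not the biology of any particular
genome. On the fixture the genome-wide TSS500/promoter densities exceed the
planted per-zone rates because the DEG and high-burden genes deliberately
carry extra TSS motifs.

## Problem sizes and numerics

Tests and the acceptance script run on 3 × 300 kb chromosomes with 120
genes (~750 planted motifs), 1000 × 2 kb fuzz sequences for oracle
equivalence and 300 for symmetry properties — sizes chosen so the whole
suite completes in well under a minute while every planted count is large
enough for its tolerance. Window means compare as IEEE doubles of an
integer sum divided by the window length, identically in the detector and
the oracle, so threshold comparisons are bit-reproducible. Ties in G4SDF
(`cd == td`) are reported as `tie` with fold 1.0. Densities are compared at
full precision in tests (tolerance 0.005 where a 2 dp report is checked).

## Known limitations

- Promoter/TSS regions use the gene feature's bounds; alternative TSSs and
  isoform-resolved regions are out of scope.
- The detector reports refined-interval scores; tools that report the
  maximal window mean instead will rank hits slightly differently (the
  value is retained as a secondary column).
- Centromere statistics require user-supplied coordinates (seq_id, start,
  end TSV); none are bundled.
- GO/KEGG enrichment is not computed; the pipeline exports the gene lists
  that downstream enrichment tools consume.
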