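# Methods

## The analysis

`icgh` implements *in silico* comparative genome hybridization (CGH): short
reads from a query bacterial genome of unknown sequence are mapped onto an
annotated reference genome from a closely related strain, and annotated
regions that attract essentially no reads are inferred to be absent from the
query.  The procedure is:

1. **Dissection.**  The reference is cut into an ordered series of *gene*
   segments (one per protein-coding or RNA gene, feature extents exactly) and
   *IGR* segments (one per positive gap between consecutive genes).
   Overlapping genes each keep their full extent and the swallowed gap yields
   no IGR.  On circular chromosomes the leading and trailing gaps merge into
   a single wrap-around IGR.  Coordinates are 0-based half-open internally;
   GFF3 and SAM are converted at the boundary.
2. **Coverage rate.**  For each segment, the percentage of its nucleotides
   covered by at least one mapped read — breadth, not depth.  Exact integer
   covered-base counts are kept; nothing is rounded before export.
3. **LCR calling.**  Segments with coverage rate strictly below 20% are
   low-coverage-rate (LCR) segments.  The threshold is configurable; the
   inequality is strict, so a rate of exactly 20.0 is *not* LCR.
4. **Content summaries.**  Per-query LCR gene counts and percentages of the
   reference gene total (reported to the nearest integer, except values below
   1% which keep two decimals); the nonredundant union and Venn partition of
   LCR genes across 2–4 queries; expected query genome size = reference size
   − total LCR segment length; per-position coverage tracks and rate
   histograms (bins [0,10) … [90,100], last bin closed).
5. **Clusters.**  Maximal runs of consecutive LCR segments holding ≥2 LCR
   genes are LCR gene clusters (candidate genomic islands); runs holding
   exactly one LCR gene yield an independent LCR gene; IGR-only runs are
   recorded but form no cluster.  By default any non-LCR segment breaks a
   run; `igr_gap_tolerance` optionally lets short non-LCR IGRs bridge.  Runs
   may join across the origin of circular genomes.
6. **Flank classification.**  Each cluster's end-windows are searched for
   (a) a tRNA gene with a same-orientation, ≥90%-identity copy covering ≥70%
   of its length in the opposite window (window 2,000 bp); (b) a generic
   direct repeat — the optimal local alignment of the two end-windows spans
   ≥15 columns at ≥85% identity (window 150 bp); (c) annotated same-family IS
   copies in both windows (window 2,000 bp).  Annotated tRNA bases are masked
   (→ N) before the direct-repeat search, so tRNA-derived repeats are tallied
   only in their own class.  Cross-query counts are over nonredundant
   clusters (identical reference spans deduplicated).
7. **Gene properties.**  GC3 (percentage of G/C at third codon positions,
   terminal stop excluded, ambiguous thirds skipped) and CAI (geometric mean
   of per-codon relative adaptedness w against a highly expressed reference
   set; Met, Trp and stops excluded) under translation table 11, computed
   strictly on the annotated coding strand.  Low GC3 and CAI in the LCR union
   indicate foreign (horizontally acquired) origin.

## Read mapping

The built-in mapper is ungapped and exact by contract: a read maps at a
reference position iff the full-length comparison there has at most
`max_mismatches` (default 3) mismatches, on either strand; `N` never matches.
Seeding is purely an accelerator: the read is split into `max_mismatches + 1`
disjoint exact-match chunks of length `min(seed_k, read_len // (max_mismatches
+ 1))` (pigeonhole: any valid location leaves at least one chunk exact), so
the hit set provably equals a naive all-positions scan — this is asserted
against such a scan in the tests.  Multi-mapped reads contribute coverage at
every passing location by default, because coverage *breadth* is the
presence/absence signal and dropping repeats would spuriously flag multicopy
genes (e.g. duplicated transposases, tRNAs) as absent; `--best-only` keeps
the single best location (fewest mismatches, then leftmost, forward strand
first).  Gapped or quality-aware alignment is delegated to external aligners
via SAM/BAM ingestion, where a base is covered iff a non-secondary,
non-unmapped alignment block overlaps it (clipped bases do not cover).
Mapping is linear even for circular references; only reads spanning the
origin junction are affected, a ≤ read-length effect at one locus.

## Local alignment

The repeat searches use an affine-gap Smith–Waterman (Gotoh) aligner
(match +2, mismatch −3, gap open −5, gap extend −2; a length-L gap costs
open + L·extend).  The optimal score and one optimal alignment are reported,
with a deterministic tie-break (smallest end coordinates, preferring
diagonal moves in the traceback).  Alignment identity is matches / aligned
columns, gap columns included.  The implementation is a numba kernel; tests
check score equality against an exhaustive substring-pair dynamic program on
short sequences and score symmetry.

## The synthetic generator

No real sequencing data ships with the package; the generator provides the
study conditions and the ground truth for every downstream stage.

* **Reference.**  Alternating gene/IGR layout.  Gene lengths are 90 bp plus a
  geometric excess (mean 900 bp total); IGR lengths 30 bp plus geometric
  excess (mean 150 bp); the floors avoid degenerate segments.  Genes carry a
  start codon, an in-frame body sampled from a codon-usage model (no internal
  stops by construction) and a stop codon, on a random strand.  Background GC
  is 0.70, typical of GC-rich soil actinobacteria.  A subset of gene slots
  becomes tRNA genes (~1 per 40 genes) and IS elements (700–1,000 bp,
  family-labelled copies ~22% diverged from a family consensus) are spliced
  into some IGRs.  Genomes are generated linear but flagged circular by
  default, matching bacterial chromosomes.
* **Codon models.**  Native genes prefer G/C-ending codons with probability
  0.70 within each synonymous family.  "Highly expressed" genes (~5%)
  concentrate 85% of each family's mass on its preferred codon and serve as
  the default CAI reference set.  Foreign genes use the native model with GC3
  shifted by −15 percentage points, so the horizontal-transfer signature
  (lower GC3 and CAI) is recoverable by construction.
* **Edits.**  Query genomes are derived by excising deletions (whole segment
  runs: clustered blocks of 2–12 genes and isolated single genes, targeted at
  planted foreign blocks) and splicing foreign segments into IGR anchor
  points.  The truth manifest records every edit, the genes fully/partially
  removed, and the expected size (reference − deleted + inserted), which
  always equals the realized query length.  Flanking elements for planned
  deletions — an identical 20 bp repeat, two copies of a reference tRNA, or
  two ~25%-diverged same-family IS copies — are spliced into the reference
  IGRs just outside the deletion ends before queries are derived, so the
  flank classifier can be scored against planted truth.
* **Reads.**  `ceil(depth × genome / read_len)` single-end 50 bp reads,
  uniform start positions, both strands, independent per-base substitutions
  (no indel errors, no pairing, nucleotide space).  All generator operations
  are bit-deterministic given their seeds.

The benchmark (`make_demo`) uses a 200-gene reference (~220 kb) and four
queries: no loss, and 5% / 15% / 30% of genes deleted as nested subsets of
the planted blocks, the heaviest query also receiving foreign insertions.
Depth is 20×, error 1%.  These problem sizes keep a full run under a minute
while leaving every coverage-rate decision far from its threshold at 20×
depth.

## What the synthetic data does and does not show

Passing recovery tests shows the pipeline's logic is correct end to end:
deleted segments are called LCR, clusters and their flanks are recovered
exactly, and the composition statistics separate the planted foreign genes.
Real data differ in ways the generator deliberately omits: shared ancestral
repeats and paralogy between strains, mapper-specific sensitivity (the study
this emulates used a proprietary colorspace mapper whose stringency is
unknown), uneven library coverage, indel errors, and genuinely diverged (not
merely deleted) genes that produce intermediate coverage rates.  Absolute
agreement with any particular real dataset is therefore not implied.

## Numerical and design choices

* Percentage reporting: nearest integer, ties away from zero; values below
  1% keep two decimals.  The rule is configurable (`half_even` available)
  because no single rule reproduces every published rounding.
* The LCR boundary is strict (<); rate arithmetic is exact integer counts.
* Segment export is 1-based inclusive start TSV with 4-decimal rates; all
  internal computation is unrounded.
* The direct-repeat window (150 bp) is deliberately tighter than the tRNA
  window (2,000 bp): excision-generating repeats abut the deletion junctions,
  and a small search space keeps coincidental near-exact ≥15-column
  alignments rare.  In uniform-composition random windows the false-positive
  rate is ~1%; at GC 0.70 it rises to ~5–10% per cluster, so at GC-rich
  backgrounds the generic direct-repeat class is expected to pick up
  occasional coincidental calls and category assignments are not strictly
  exclusive in general.
* Relative adaptedness ties (two codons with equal top counts) each keep
  w = 1; the preferred-codon label breaks ties lexicographically.  Unobserved
  families are uninformative (w = 1 throughout); zero-count codons in
  observed families are floored at 0.01.
* `nonredundant cluster` across queries means an identical (start, end)
  reference span.

## Known limitations

* The mapper is ungapped and indel-blind; use an external aligner and SAM
  ingestion for real data.
* Flank classification inspects present-day annotation only; elements eroded
  by subsequent rearrangement are invisible, and the direct-repeat class has
  the composition-dependent false-positive behaviour described above.
* Wrap-around handling assumes no feature itself spans the origin.
* GC3/CAI are computed internally from the annotation; they are not intended
  to reproduce any external database's precomputed values.
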