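# Methods

## Scope and model

isogrow implements a reference-free long-read transcriptome workflow for a
two-group (fast-growing BG vs slow-growing SG), two-tissue (frontal/parietal
bone F, vertebra V), three-replicate design. Because no genome is assumed,
every structural inference — isoform clustering, alternative splicing,
coding potential, microsatellites — is made from the transcript sequences
alone. The package pairs each analysis stage with a synthetic-data generator
that plants the corresponding truth, so correctness claims are made against
construction rather than against an external reference.

## Read filtering and FLNC classification

CCS-like reads carry a pass count and a quality estimate; the filter keeps
`passes >= 3` and `quality > 0.9` (the quality cut is strict). Full-length
classification requires the 5' primer, the 3' primer and a polyA tail to be
observed simultaneously. Design choices where the convention was open:

- "Near a terminus" means within 100 bp of a read end; primer hits clear of
  both terminal windows are internal and mark the read chimeric regardless
  of other evidence.
- Primer matching is substitution-only (Hamming) over a sliding window with
  `max_mismatch = 3` by default. This keeps the detector exactly checkable
  against a brute-force oracle; it also means reads whose primer carries an
  indel are classified nFL rather than rescued, which only lowers FL yield.
- polyA detection reports the 3'-most run of ≥ 20 bases containing at most
  2 non-A bases, searched after masking the 3' primer. Because the tolerant
  window can absorb transcript bases adjacent to the tail, trimming cuts at
  the contiguous pure-A run instead; the generator ends transcripts on a
  non-A base so trimming is exact on clean reads.
- Coordinates are 0-based, half-open everywhere.

## Clustering, consensus and families

Greedy longest-first clustering assigns each sequence to the first cluster
whose representative matches at identity ≥ threshold, where identity is
`1 − edit_distance / len(shorter)` with the shorter sequence aligned as an
infix of the longer (edlib, mode HW). Ties break longest-first then
lexicographic, making every greedy pass deterministic. Raw FLNC reads carry
residual error on both sides of a comparison, so the pipeline clusters reads
at 0.95 and applies the canonical 0.99 cutoff to the polished consensi at
the dedup step; both thresholds are configurable.

Consensus is per-column majority over members globally aligned to the
representative: substitutions in the representative are outvoted, columns a
majority of members lack are dropped, and insertions relative to the
representative are ignored (they cannot be placed without a second
alignment pass). A representative base that a minority deletes is retained.
At ~1 % read error and ≥ 3 members the consensus error is dominated by
representative deletions, roughly a third of the input error rate.

Gene families connect transcripts whose 8-mer count profiles reach cosine
similarity ≥ 0.5 (pairs prefiltered by ≥ 5 shared distinct 8-mers); families
are the connected components. Isoforms sharing all but one exon-sized block
score ≈ sqrt(1 − b/L) ≈ 0.9, unrelated ~kb sequences ≈ 0.02, so the
threshold sits in a wide margin.

## Alternative splicing

HSPs come from iterated local alignment with masking: the best local
alignment (match +1, mismatch −2, gap open −5, extend −2; Biopython
PairwiseAligner) is split at internal gaps longer than 30 bp on either axis,
pieces scoring ≥ 50 are recorded, their footprints are masked on both
sequences, and the search repeats. The split step matters: an affine-gap
optimum happily bridges a skipped exon block with one long gap, whereas the
event definition needs the flanks as two separate HSPs. The 30 bp split
threshold lies safely between residual-error indels (a few bp) and
reportable AS gaps (> 100 bp); the 50-point score floor is the explicit
default for an otherwise unstated alignment parameter.

A pair is reported iff: both transcripts exceed 1,000 bp; exactly two HSPs
survive (three or more are rejected as ambiguous — the criteria describe a
single AS gap); the HSPs are collinear with footprint overlap ≤ 5 bp on
either axis; the gap, measured on the transcript carrying the extra
sequence, exceeds 100 bp and lies ≥ 100 bp from that transcript's 5' and 3'
ends. Events are reported once per unordered pair and are orientation
symmetric. Event types (exon skip vs alternative sites) are deliberately not
classified: without a genome the distinction is not identifiable. Gap
coordinates can shift a few bases when the junction sits in locally repeated
context (co-optimal gap placement); gap length is invariant.

All-vs-all alignment is avoided by a shared-15-mer prefilter (≥ 30 distinct
shared 15-mers, ignoring 15-mers held by > 50 transcripts); it is bypassable
(`prefilter=False`) so oracle tests can scan exhaustively.

## ORFs and coding potential

Six-frame scanning with ATG as the only start and TAA/TAG/TGA stops.
Stop-free segments are classified per start/stop presence: both → complete
(reported from the first ATG); stop only, reading from the transcript edge →
5'-partial; ATG running off the 3' edge → 3'-partial; a fully open frame →
internal. `min_aa = 100` mirrors the common ORF-caller default and is the
main driver of complete-ORF counts.

The lncRNA filter keeps the consensus-intersection contract of multi-tool
coding-potential pipelines while remaining self-contained: three independent
predicates (longest ORF ≥ 100 aa; longest ORF covering ≥ 30 % of the
transcript; Fickett TESTCODE-style statistic ≥ 0.95) each vote, and a
transcript is a lncRNA candidate only when it exceeds 200 bp and every
predicate votes non-coding. The Fickett statistic combines per-base codon-
position bias and composition through the classic lookup tables; 0.95 is
the published coding cutoff, so random-composition transcripts (typical
scores 0.3–0.6) rarely misfire. An exon-count criterion used with
genome-aligned data is dropped: exon counts are unknowable here. The
predicate set is pluggable.

## Microsatellites

Perfect SSRs are maximal tandem runs of a primitive 1–6 bp motif meeting
minimum repeat counts {1:10, 2:6, 3:5, 4:5, 5:5, 6:5}, mined only on
transcripts > 500 bp. A run is reported at its left-maximal start; motifs
that are repetitions of shorter motifs surface at the shorter period
("AA"×6 is "A"×12). N-containing motifs are ignored. Canonical motifs
minimize over cyclic rotations only — transcripts are oriented — with a
`collapse_revcomp` option for genomic use. Adjacent loci ≤ 100 bp apart
(the cited detection tool's published default) merge into one compound
locus, counted once in summaries. Summary percentages are
`100 × class / total` rounded to two decimals, reported as 0 with a flag on
empty input.

## Expression and differential testing

FPKM is the direct formula per cell. The DE screen is a deliberately
simplified NB Wald test rather than a wrapper around an external package:
median-of-ratios size factors; per-gene method-of-moments dispersion from
the pooled within-group variance with a floor of 0.01; the group contrast
`log(mean_BG / mean_SG)` with delta-method standard error
`sqrt((1/mu_BG + alpha)/n1 + (1/mu_SG + alpha)/n2)`; and a Student-t
reference with `n1 + n2 − 2` degrees of freedom. The t reference (rather
than normal) absorbs the dispersion-estimation noise at n = 3 per group;
with it the empirical null type-I error at α = 0.05 sits inside
[0.03, 0.07] over 2,000 simulated null genes, which is the calibration
contract the test suite enforces. A 0.5 pseudocount replaces zero group
means (this shifts boundary genes and is therefore documented); genes with
total count < 10 are reported untested. BH adjustment is the classic
step-up, returned in input order. DEGs satisfy `q < 0.01` and
`|log2FC| ≥ 1`; note that with three replicates and moderate effects this
strict gate has low power — on default simulations it commonly returns no
DEGs, which is the honest behaviour of the screen at that sample size, not
a defect. Sign recovery of planted log2FC = 2 effects exceeds 95 %.

## Triage and validation math

Enrichment is the hypergeometric upper tail `P(X ≥ k)` per term, BH-adjusted
within each term type (pathways and GO separately, mirroring per-analysis
q-values); K = 0 terms are flagged and skipped. The three key-gene
strategies are: (i) participation in ≥ 2 pathways of the fixed 15-pathway
growth panel ("high participation frequency" is otherwise unquantified;
2 is the configurable, logged default), (ii) ≥ 3 (GO term, category) hits
within biological regulation / immune system process / metabolic process
("more than two times" read strictly), (iii) intersection of the per-tissue
DEG sets. The report is the union with per-gene strategy provenance — the
10 + 7 + 3 = 20 arithmetic of the motivating design only sums for a union
of disjoint sets — with an `intersection` mode for the stricter reading.

Phenotype HL/BL ratios are computed from group means and rounded to four
decimals; with per-fish rows, Welch (unequal-variance) t-tests are run per
trait, flagged at p < 0.05 — appropriate at n = 3 with unequal group
variances. The BG means reproduce 0.3239 exactly; the SG means give 0.3509
by direct division, slightly below a published 0.3533, consistent with
per-fish-then-average computation upstream; both readings are surfaced and
neither is forced. qPCR fold changes follow 2^−ΔΔCt with a per-sample
reference-gene ΔCt and a calibrator group; group swap inverts the fold
exactly.

## Synthetic data: what it emulates, and what it does not

Transcripts are concatenations of exon-like blocks (5–8 blocks of
150–400 bp). A configurable fraction of coding families receives a skipped
internal block of 120–300 bp (length made a multiple of 3), placed so the
retained isoform still exceeds 1,000 bp and the junction lies ≥ 100 bp from
both ends — planted AS pairs therefore satisfy the caller's criteria by
construction. Because non-coding transcripts are their own single-isoform
genes, the AS fraction applies within coding families; truths stay
orthogonal. Planted CDSs use a deliberately non-degenerate, GC-third-
position codon usage so composition statistics see realistic bias;
non-coding transcripts are random sequence post-processed to contain no
stop-free stretch of ≥ 45 codons in any of six frames. SSR loci are planted
with extension-breaking flanks, > 120 bp apart, clear of CDS and splice
junctions, so every planted locus is recovered at exact coordinates.

Reads are primer/polyA-flanked cassettes on a random strand with uniform
per-base errors (60 % substitution, 20 % insertion, 20 % deletion at 1 % by
default — residual CCS-level error, not raw polymerase error), a 2 %
chimera rate (two concatenated cassettes), a 15 % evidence-dropout rate
(truth nFL) and a 10 % CCS-filter failure rate. Counts are NB with
log-normal baselines (log-mean 4.5, log-sd 1.0), dispersion 0.1, exact
2^log2FC group ratios for DE genes applied in both tissues, and
log-normal(0, 0.1) library-size factors. Read-length and expression
distributions are package defaults, configurable, not inferred from any
dataset. Not modelled: position-dependent quality, SMRT kinetics, subread
structure, hybrid short-read correction, alternative 5'/3' splice-site
variants (one skipped-block event type suffices to exercise the caller).
Passing tests therefore demonstrate correctness of the algorithms under
these idealized conditions, not performance on real instrument data.

## Determinism and numerics

A single global seed expands into named per-stage substreams
(`sha256(seed:stage) mod 2^31`), so any stage reproduces independently of
execution order. All greedy passes have total orderings (length, then id).
Identity denominators use the shorter sequence — "non-redundant" counts
depend on this and it matches the cited dedup tool's semantics. Tables are
tab-separated with a commented header and frozen column order; the run
manifest is written atomically and carries the config hash, seed and
per-stage record counts (wall-clock fields excluded from byte-identity
guarantees).

## Problem sizes

Default simulations use 200 genes (~230 transcripts, ~690 reads), chosen so
a full pipeline run takes about a minute on one CPU while still planting
tens of AS pairs and SSR loci; calibration checks use 2,000 null genes and
500–600-gene effect-recovery simulations. All sizes are configuration
fields.
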