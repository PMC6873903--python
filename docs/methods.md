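# Methods

This note documents the models, conventions and design choices behind
`isoseqtk`, and what the synthetic-data validation does and does not show.

## Coordinate model and splice chains

All internal coordinates are 0-based half-open; GTF/GFF3 I/O converts
to/from 1-based inclusive, BED12 passes through unchanged. Exons separated
by a zero-length gap are merged on ingestion so degenerate annotations
cannot create phantom introns.

The identity key for isoform comparison is the **splice chain**: the
ordered list of intron `(donor, acceptor)` pairs in genomic orientation
(donor = intron start = exon end; acceptor = intron end = next exon start,
regardless of strand). Splice-site identity is exact — same coordinate,
same strand, no fuzz window — because the classification taxonomy
(known / novel isoform) is defined by exact sharing of splice sites.
Biological 5′/3′ roles are resolved from the strand only where they matter
(A5SS vs A3SS typing).

## Read classification

A full-length molecule reads `5′ primer — insert — poly(A) — 3′ primer`.
Primer matching is semi-global (free end gaps on the read; edlib infix
alignment) at `min_primer_identity` = 0.8 within an `end_window` = 100 bp
at each read end; a match with that identity anywhere *outside* both end
windows is concatemer evidence and makes the read chimeric. The poly(A)
tail is the leftmost terminal A-run (after trimming a terminal 3′ primer)
of ≥ 8 bases with ≤ 1 non-A. Both orientations are searched and the one
with more full-length evidence wins (tie → given orientation). Length
filters label reads < 50 bp `subthreshold` and < 300 bp `short`, both read
as strict inequalities. The vendor pipeline the thresholds mimic does not
publish its internals, so all of these are configurable (`PrimerConfig`).

## Collapse and classification

Alignments are inputs (block-level records with read coverage and
identity); filtering keeps coverage ≥ 0.85 **and** identity ≥ 0.90, both
inclusive (the thresholds are stated as minima). Multi-exon alignments
merge when they share (chromosome, strand, splice chain) and their 3′ ends
lie within `end_tolerance_3p` = 100 bp (single linkage); 5′ ends merge
without limit, reflecting 5′ degradation of full-length reads. The
representative model takes the furthest 5′/3′ extents of its members,
preserving maximal UTR evidence. Single-exon alignments merge at
reciprocal overlap ≥ 0.5, iterated to a fixed point so collapsing is
idempotent. All outputs are deterministically ordered (coordinate, then
lexicographic id).

Classification against the reference: *known isoform* = identical chain to
a reference transcript of an overlapping same-strand locus; for single-exon
transcripts, which carry no splice sites, "identical chain" is read as
reciprocal overlap ≥ 0.5 with a single-exon reference transcript. *Novel
isoform of known gene* = ≥ 1 shared splice site, or same-strand exonic
overlap when no site is shared (such calls carry `shared_sites = 0` so they
can be re-binned). *Novel gene* = neither. The matched locus maximizes
shared sites, ties broken by exonic overlap then lexicographic id. Novel
genes are single-linkage clusters under "same chromosome and strand,
exonic overlap ≥ 1 bp".

## AS event typing

Events are detected between transcript pairs by decomposing the two site
sequences into *bubbles*: regions of difference delimited by anchors
(splice sites shared by both transcripts, position **and** role). Each
bubble is matched against the five local templates — IR (intron vs
containing exon), ES (exon strictly inside an intron whose both boundaries
are shared), A5SS/A3SS (single differing site of equal role; the 5′/3′
label follows the strand), MXE (two non-overlapping alternative exons with
shared outer flanks) — and anything else is `complex`, counted separately
from the five-type totals. Locus-level detection unions all pairs and
deduplicates by (type, region, inclusion form, exclusion form),
accumulating witness pairs; this prevents quadratic inflation in
many-isoform loci while keeping one record per distinct structure. Pure
5′/3′ end differences produce no event.

## APA calling

Read 3′-end positions cluster per gene by single linkage with a gap ≤ 24 bp
(a conventional clustering window for long-read 3′ ends; configurable).
Clusters with ≥ 2 supporting reads become sites at the modal position
(ties resolved toward the most 3′ position given the strand); smaller
clusters are discarded. The APA fraction is the percentage of genes with
≥ 2 sites among genes with ≥ 1.

## Fusion criteria

Criteria A–D are applied literally to the complete, locus-merged hit set of
one read. Hits with overlapping spans merge first, so split alignments
within one gene cannot fake criterion A. Criterion D (≥ 10 kb) applies only
to same-chromosome pairs — distance is undefined across chromosomes, and
inter-chromosomal fusions must remain callable — and is measured between
nearest span edges, the conservative reading. The ≥ 1 bp per-locus floor is
nearly vacuous as stated; it is implemented literally and configurable.

## lncRNA rules

Candidate = exonic length > 200 bp, ≥ 2 exons (`min_exons` configurable to
reproduce a stricter > 2-exon reading), and non-coding by *all four*
predictor verdicts (intersection rule; verdicts are inputs). Positional
categories use the precedence **sense > intronic > antisense > lincRNA**:
same-strand exonic evidence is the strongest signal, full containment in an
intron (with no exonic overlap on either strand) next, opposite-strand
exonic overlap next, and lincRNA requires no overlap with any coding locus
span. Transcripts overlapping a locus without matching any rule are
`unclassified`. Target pairing is positional only (edge-to-edge distance
≤ 100 kb, relation up/downstream in the lncRNA's orientation); base-pairing
energetics are outside this package's scope and can be joined on from an
external score table.

## SSR rules

Maximal perfect tandem repeats of primitive 1–6 bp motifs (a motif that is
itself periodic is never reported — `AA` is a mono run), thresholds
10/6/5/5/5/5 units, sequences < 500 bp skipped, non-ACGT breaks runs. Runs
are anchored leftmost; only complete repeat units count. Overlaps between
different unit sizes are resolved longest-first (tie → smaller unit), so
reported simple SSRs never overlap. SSRs separated by ≤ 100 bp merge into
one compound record.

## Expression and DET calling

FPKM = 10⁹ · count / (library size · transcript length). log₂FC is SW
relative to FW, with +∞ / −∞ when exactly one condition is silent and NA
when both are. The per-transcript p-value provider is pluggable; the
default is a **moderated t-test** on log₂(FPKM + 1): per-transcript pooled
variances are shrunk toward a scaled inverse chi-square prior fitted by
moments on log s² (the classic empirical-Bayes squeeze), giving
t-statistics with d₀ + n₁ + n₂ − 2 degrees of freedom. At two or three
replicates per condition this information sharing is what makes testing
workable at all: a plain Welch test discards it, and an exact permutation
test has a p-value floor of 1/C(6,3) = 0.05 at n = 3 and can never clear an
FDR < 0.05 threshold — both remain available as alternatives
(`welch_log_test`, `permutation_log_test`). P-values are BH-adjusted; a DET
requires FDR < 0.05 and |log₂FC| ≥ 1 (±∞ counts toward its sign; NA never
flags). Genes with ≥ 2 DETs group into `similar` (one sign) or `opposite`
(both signs) patterns. 2^−ΔΔCT is provided for qPCR cross-checks.

## Synthetic data: what it emulates and what it does not

The default plan builds 2 × 500 kb chromosomes carrying 60 well-separated
genes (6 single-exon; multi-exon genes have 4–6 exons of 150–220 bp and one
roomy 0.9–1.2 kb intron), ~82 isoforms (one planted variant per AS event:
6 IR, 5 ES, 4 A5SS, 4 A3SS, 3 MXE), 12 genes withheld from the reference as
novel genes, ~1,300 reads (per-isoform FLNC reads with 5′ truncation up to
30 % of the transcript, NFL/chimeric/short/subthreshold classes, mixed
orientations), 30 below-threshold alignments, 42 genes with supported
poly(A) sites (12 of them APA genes, spacing 80 bp ≫ the 24 bp window),
6 fusions plus one near-miss per criterion, 5 lncRNAs per category, 23
planted SSR groups, and a 200-transcript negative-binomial count matrix
(3 + 3 replicates, dispersion 0.05, 40 DETs at |log₂FC| = 2, six
two-isoform pattern genes). These sizes keep the full suite under a minute
on one CPU while exercising every rule at least a few times; they are
scaled-down study conditions, not estimates of the original data volumes.

The genome background is scrubbed of incidental tandem repeats before SSR
planting (and transcript sequences re-checked across exon junctions), so
the planted SSR truth is exhaustive and recovery can be asserted with zero
false positives. Planted runs sit at offset 65 inside each host gene's
largest exon with ≥ 59 bp margins, so sibling isoforms whose splice
boundaries shift by < 60 bp contain a planted run either completely or not
at all — never as a partial repeat. One SSR host per gene prevents two
planted groups from landing within compound distance in any one transcript.

Deliberate simplifications: reads carry no sequencing error by default
(an optional uniform substitution model exists; the zero-error setting is
what makes 100 % truth recovery a meaningful contract), alignments are
exact (no alignment-induced block noise), primer sequences are fixed
synthetic 25-mers, expression counts are independent across transcripts
(no isoform-level count ambiguity), and no quality values are simulated.
Passing the truth-recovery suites therefore demonstrates the correctness of
the decision rules, not robustness to base-calling or alignment error.

Determinism: every stage draws from its own stream derived from
`(seed, stage)`, so outputs are byte-identical across runs and adding a
stage never perturbs earlier ones.

## Numerical conventions

Percentages are half-up rounded to two decimals (or the printed precision
when one decimal is conventional). Ties are broken deterministically
everywhere: coordinates first, then lexicographic ids; modal poly(A)
positions toward the 3′ end; SSR overlaps toward longer then smaller-unit
motifs. BH adjustment is delegated to statsmodels and cross-checked against
a brute-force step-up implementation in the tests.

## Known limitations

- The complex-AS residual is counted but not sub-typed (no alternative
  first/last exon classes).
- Quantitative splicing (PSI) and NMD prediction are out of scope.
- The collapse step assumes alignments already strand-assigned; unstranded
  alignments are not rescued.
- lncRNA target pairing is positional; complementarity scoring must come
  from outside.
- The moderated test assumes roughly variance-stabilized log-scale data;
  at extreme low counts a count-based model would be preferable.
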