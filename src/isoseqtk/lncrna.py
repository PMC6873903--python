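"""Long non-coding RNA candidate selection, positional classes, target pairing.

Coding-potential calls come from external predictors (CPC, CNCI, CPAT and a
Pfam domain search); a transcript is a lncRNA candidate only when *all four*
agree it is non-coding (intersection rule), it exceeds the minimum length
and it has at least ``min_exons`` exons.

Candidates are then classified by position relative to protein-coding genes
with the precedence sense > intronic > antisense > lincRNA:

* ``sense``     — exonic overlap with a same-strand coding transcript;
* ``intronic``  — contained entirely within an intron of a coding
  transcript, with no exonic overlap on either strand;
* ``antisense`` — exonic overlap with an opposite-strand coding transcript;
* ``lincRNA``   — no overlap with any coding locus span (intergenic);
* ``unclassified`` — overlaps a coding locus without matching any rule
  (e.g. straddles a gene boundary intron-only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import AnnotationIndex, GenomicInterval, TranscriptModel

VERDICT_SOURCES = ("CPC", "CNCI", "CPAT", "PFAM")
LNC_CATEGORIES = ("lincRNA", "intronic", "antisense", "sense", "unclassified")


@dataclass(frozen=True)
class LncClassification:
    transcript_id: str
    category: str


def select_lnc_candidates(
    ts: Sequence[TranscriptModel],
    verdicts: Mapping[str, Mapping[str, str]],
    min_len: int = 200,
    min_exons: int = 2,
) -> list[TranscriptModel]:
    """Intersection filter: long, spliced, and non-coding by all predictors.

    ``verdicts`` maps transcript id -> {source: "coding"|"noncoding"} for
    the sources in :data:`VERDICT_SOURCES`.  Transcripts with a missing
    source are skipped with a warning.  The length filter is strict
    (``> min_len``) and the exon filter inclusive (``>= min_exons``).
    """
    kept = []
    for t in ts:
        v = verdicts.get(t.id)
        if v is None or any(src not in v for src in VERDICT_SOURCES):
            warnings.warn(
                f"transcript {t.id}: incomplete coding-potential verdicts; skipped",
                stacklevel=2,
            )
            continue
        if t.exonic_length <= min_len or t.n_exons < min_exons:
            continue
        if all(v[src] == "noncoding" for src in VERDICT_SOURCES):
            kept.append(t)
    return kept


def classify_lnc_position(
    lnc: TranscriptModel, ann: AnnotationIndex
) -> LncClassification:
    """Positional class of one lncRNA against the coding annotation."""
    span = lnc.span
    query = GenomicInterval(span.chrom, span.start, span.end, ".")
    loci = ann.overlapping_loci(query)
    if not loci:
        return LncClassification(lnc.id, "lincRNA")

    exonic_same = False
    exonic_opposite = False
    in_intron = False
    for locus in loci:
        for ref in ann.locus_transcripts(locus.id):
            ov = lnc.exonic_overlap_bp(ref)
            if ov > 0:
                if ref.strand == lnc.strand:
                    exonic_same = True
                else:
                    exonic_opposite = True
            for intron in ref.introns():
                if intron.start <= span.start and span.end <= intron.end:
                    in_intron = True

    if exonic_same:
        return LncClassification(lnc.id, "sense")
    if in_intron and not exonic_opposite:
        return LncClassification(lnc.id, "intronic")
    if exonic_opposite:
        return LncClassification(lnc.id, "antisense")
    return LncClassification(lnc.id, "unclassified")


def classify_lnc_positions(
    lncs: Iterable[TranscriptModel], ann: AnnotationIndex
) -> dict[str, str]:
    return {l.id: classify_lnc_position(l, ann).category for l in lncs}


def pair_lnc_targets(
    lnc: TranscriptModel,
    ann: AnnotationIndex,
    max_dist: int = 100_000,
) -> list[tuple[str, int, str]]:
    """Candidate cis targets: coding loci within ``max_dist`` of the lncRNA.

    Returns (locus id, edge-to-edge distance, relation) tuples where the
    relation is ``overlapping`` (distance 0), ``upstream`` or ``downstream``
    of the lncRNA in its own strand orientation.
    """
    span = lnc.span
    pairs = []
    query = GenomicInterval(
        span.chrom, max(0, span.start - max_dist), span.end + max_dist, "."
    )
    for locus in ann.overlapping_loci(query):
        g = locus.span
        if g.chrom != span.chrom:
            continue
        if g.overlaps(span):
            pairs.append((locus.id, 0, "overlapping"))
            continue
        dist = span.gap_to(g)
        if dist > max_dist:
            continue
        before = g.end <= span.start  # gene lies genomically left of the lncRNA
        if lnc.strand == "+":
            relation = "upstream" if before else "downstream"
        else:
            relation = "downstream" if before else "upstream"
        pairs.append((locus.id, dist, relation))
    pairs.sort(key=lambda p: (p[1], p[0]))
    return pairs
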