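"""Collapse aligned long reads into non-redundant isoforms and classify them.

The pipeline stage mirrors ToFU-style collapsing: alignments passing
coverage/identity filters are grouped by identical splice chain (multi-exon)
or by reciprocal overlap (single-exon) and merged into one representative
transcript model per group.  Models are then compared against the reference
annotation:

* ``known_isoform``            — splice chain identical to a reference
  transcript of an overlapping same-strand locus;
* ``novel_isoform_known_gene`` — shares at least one splice site with such a
  locus (or, lacking shared sites, has same-strand exonic overlap; for
  single-exon models exonic overlap is the criterion);
* ``novel_gene``               — absent from every annotated locus.

Transcripts classified ``novel_gene`` are clustered into novel loci by
single-linkage exonic overlap on one strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import (
    AnnotationIndex,
    GeneLocus,
    GenomicInterval,
    SpliceChain,
    TranscriptModel,
    build_splice_chain,
    reciprocal_overlap,
    shared_splice_sites,
)

CATEGORIES = ("known_isoform", "novel_isoform_known_gene", "novel_gene")


@dataclass(frozen=True)
class ReadAlignment:
    """Block-level alignment of one read to the genome (alignment is an input)."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]
    read_coverage: float = 1.0
    identity: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.read_coverage <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise ValueError("coverage and identity must be in [0,1]")
        if not self.blocks:
            raise ValueError(f"alignment {self.read_id}: no blocks")

    def to_transcript(self) -> TranscriptModel:
        return TranscriptModel(
            id=self.read_id, chrom=self.chrom, strand=self.strand, exons=self.blocks
        )


@dataclass(frozen=True)
class CollapseParams:
    min_coverage: float = 0.85
    min_identity: float = 0.90
    end_tolerance_3p: int = 100
    single_exon_min_overlap: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_identity", "single_exon_min_overlap"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0,1]")


@dataclass(frozen=True)
class TranscriptCategory:
    label: str
    matched_locus: str | None
    shared_site_count: int


def filter_alignments(
    alns: Iterable[ReadAlignment], p: CollapseParams
) -> list[ReadAlignment]:
    """Keep alignments with coverage and identity at or above the thresholds."""
    return [
        a
        for a in alns
        if a.read_coverage >= p.min_coverage and a.identity >= p.min_identity
    ]


def _merge_members(
    members: list[TranscriptModel], new_id: str
) -> TranscriptModel:
    """One representative model spanning the furthest extents of its members."""
    chain = build_splice_chain(members[0])
    start = min(m.start for m in members)
    end = max(m.end for m in members)
    bounds = [start]
    for donor, acceptor in chain.introns:
        bounds.extend((donor, acceptor))
    bounds.append(end)
    exons = tuple(
        GenomicInterval(members[0].chrom, s, e, members[0].strand)
        for s, e in zip(bounds[::2], bounds[1::2])
    )
    return TranscriptModel(
        id=new_id, chrom=members[0].chrom, strand=members[0].strand, exons=exons
    )


def collapse_isoforms(
    alns: Sequence[ReadAlignment],
    p: CollapseParams | None = None,
    member_registry: dict[str, list[str]] | None = None,
) -> list[TranscriptModel]:
    """Collapse filtered alignments into non-redundant transcript models.

    Multi-exon alignments merge when they share (chrom, strand, splice chain)
    and their 3' ends fall within ``end_tolerance_3p`` of each other
    (single linkage); 5' ends merge without limit, reflecting 5'
    degradation.  Single-exon alignments merge when reciprocally overlapping
    by at least ``single_exon_min_overlap`` (iterated to a fixed point, so
    collapsing is idempotent).  Output order is deterministic:
    (chrom, start, id).  If ``member_registry`` is supplied it is filled with
    model id -> sorted member read ids.
    """
    if p is None:
        p = CollapseParams()
    models = [a.to_transcript() for a in alns]

    # --- multi-exon: group by identical chain, then 3'-end single linkage
    multi: dict[tuple[str, str, tuple], list[TranscriptModel]] = {}
    single: dict[tuple[str, str], list[TranscriptModel]] = {}
    for m in models:
        if m.is_multi_exon:
            key = (m.chrom, m.strand, build_splice_chain(m).introns)
            multi.setdefault(key, []).append(m)
        else:
            single.setdefault((m.chrom, m.strand), []).append(m)

    merged: list[tuple[TranscriptModel, list[str]]] = []
    for key in sorted(multi, key=lambda k: (k[0], k[1], k[2])):
        group = sorted(multi[key], key=lambda m: (m.three_prime_end(), m.id))
        # single-linkage clusters on the 3'-end coordinate
        clusters: list[list[TranscriptModel]] = []
        for m in group:
            if (
                clusters
                and abs(m.three_prime_end() - clusters[-1][-1].three_prime_end())
                <= p.end_tolerance_3p
            ):
                clusters[-1].append(m)
            else:
                clusters.append([m])
        for members in clusters:
            rep = _merge_members(members, members[0].id)
            merged.append((rep, sorted(m.id for m in members)))

    # --- single-exon: reciprocal-overlap single linkage, iterated to fixpoint
    for key in sorted(single):
        clusters = [[m] for m in sorted(single[key], key=lambda m: (m.start, m.id))]
        reps = [m.span for c in clusters for m in c[:1]]

        def _rep(cluster: list[TranscriptModel]) -> GenomicInterval:
            return GenomicInterval(
                cluster[0].chrom,
                min(m.start for m in cluster),
                max(m.end for m in cluster),
                cluster[0].strand,
            )

        changed = True
        while changed:
            changed = False
            i = 0
            while i < len(clusters) - 1:
                a, b = _rep(clusters[i]), _rep(clusters[i + 1])
                if reciprocal_overlap(a, b) >= p.single_exon_min_overlap:
                    clusters[i] = clusters[i] + clusters.pop(i + 1)
                    changed = True
                else:
                    i += 1
        for members in clusters:
            span = _rep(members)
            rep = TranscriptModel(
                id=min(m.id for m in members),
                chrom=span.chrom,
                strand=span.strand,
                exons=(span,),
            )
            merged.append((rep, sorted(m.id for m in members)))

    merged.sort(key=lambda pair: (pair[0].chrom, pair[0].start, pair[0].id))
    if member_registry is not None:
        for rep, members in merged:
            member_registry[rep.id] = members
    return [rep for rep, _ in merged]


def classify_transcript(
    t: TranscriptModel, ann: AnnotationIndex
) -> TranscriptCategory:
    """Classify one collapsed model against the reference annotation."""
    overlapping = ann.overlapping_loci(t.span, same_strand=True)
    if not overlapping:
        return TranscriptCategory("novel_gene", None, 0)

    chain = build_splice_chain(t)
    candidates = []  # (shared_sites, exonic_overlap, locus, exact, exon_overlap_bool)
    for locus in overlapping:
        ref_ts = ann.locus_transcripts(locus.id)
        exact = False
        for ref in ref_ts:
            ref_chain = ann.chain(ref.id)
            if chain.introns and ref_chain.introns == chain.introns:
                exact = True
            elif not chain.introns and not ref_chain.introns:
                # single-exon vs single-exon reference: exact when the
                # exons reciprocally overlap (no splice sites to compare)
                if reciprocal_overlap(t.span, ref.span) >= 0.5:
                    exact = True
        shared = len(set(chain.sites()) & ann.locus_splice_sites(locus.id))
        exon_ov = sum(t.exonic_overlap_bp(ref) for ref in ref_ts)
        candidates.append((shared, exon_ov, locus, exact))

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2].id))
    shared, exon_ov, best, _ = candidates[0]
    if any(c[3] for c in candidates):
        exact_best = min((c for c in candidates if c[3]), key=lambda c: (-c[0], -c[1], c[2].id))
        return TranscriptCategory("known_isoform", exact_best[2].id, exact_best[0])
    if shared >= 1 or exon_ov >= 1:
        return TranscriptCategory("novel_isoform_known_gene", best.id, shared)
    return TranscriptCategory("novel_gene", None, 0)


def classify_transcripts(
    ts: Iterable[TranscriptModel], ann: AnnotationIndex
) -> dict[str, TranscriptCategory]:
    return {t.id: classify_transcript(t, ann) for t in ts}


def cluster_novel_loci(
    novel: Sequence[TranscriptModel], prefix: str = "NOVELG"
) -> list[GeneLocus]:
    """Single-linkage clustering of novel transcripts into novel gene loci.

    Two transcripts link when they are on the same chromosome and strand and
    their exons overlap by at least 1 bp.
    """
    order = sorted(novel, key=lambda t: (t.chrom, t.strand, t.start, t.id))
    parent = list(range(len(order)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for i, a in enumerate(order):
        for j in range(i + 1, len(order)):
            b = order[j]
            if (b.chrom, b.strand) != (a.chrom, a.strand) or b.start >= a.end:
                break
            if a.exonic_overlap_bp(b) >= 1:
                union(i, j)

    groups: dict[int, list[TranscriptModel]] = {}
    for i, t in enumerate(order):
        groups.setdefault(find(i), []).append(t)

    loci = []
    members_sorted = sorted(
        groups.values(), key=lambda g: (g[0].chrom, min(t.start for t in g), g[0].id)
    )
    for k, members in enumerate(members_sorted, start=1):
        span = GenomicInterval(
            members[0].chrom,
            min(t.start for t in members),
            max(t.end for t in members),
            members[0].strand,
        )
        loci.append(
            GeneLocus(
                id=f"{prefix}.{k}",
                span=span,
                transcripts=sorted(t.id for t in members),
                origin="novel",
            )
        )
    return loci


def isoform_distribution(loci: Iterable[GeneLocus]) -> dict[str, int]:
    """Histogram of isoforms per locus in bins 1,2,3,4,>=5."""
    hist = {"1": 0, "2": 0, "3": 0, "4": 0, ">=5": 0}
    for locus in loci:
        n = len(locus.transcripts)
        if n <= 0:
            continue
        hist[str(n) if n < 5 else ">=5"] += 1
    return hist
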