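"""Alternative-splicing event detection and poly(A)-site (APA) calling.

AS events are detected between transcript pairs by decomposing the two
splice chains into *bubbles*: maximal regions of structural difference
delimited by splice sites the two transcripts share (position and role).
Each bubble is matched against the five canonical local templates —

* IR   (intron retention)           — one chain splices an intron that lies
  entirely inside an exon of the other;
* ES   (exon skipping)              — one chain has an exon strictly inside
  an intron of the other, both flanking sites shared;
* A5SS / A3SS (alternative 5'/3' splice site) — two introns share one
  boundary and differ at the other; the biological 5'/3' role of the
  differing boundary is resolved via the strand;
* MXE  (mutually exclusive exons)   — each chain includes the internal exon
  the other skips, the exons do not overlap, outer flanking sites shared.

Bubbles matching no template are reported as ``complex`` and excluded from
five-type totals.  Locus-level detection takes the union over all transcript
pairs and deduplicates events structurally, accumulating witness pairs.

Poly(A) sites are called from FLNC-read 3'-end positions per gene by
single-linkage clustering with a configurable gap, keeping clusters with at
least ``min_support`` reads (two by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from .model import (
    GenomicInterval,
    StrandMismatchError,
    TranscriptModel,
    build_splice_chain,
)

EVENT_TYPES = ("IR", "ES", "A3SS", "A5SS", "MXE")

SiteSeq = tuple[tuple[int, str], ...]  # ((position, 'D'|'A'), ...)


@dataclass
class ASEvent:
    event_type: str  # IR | ES | A3SS | A5SS | MXE | complex
    region: GenomicInterval
    inclusion_form: SiteSeq
    exclusion_form: SiteSeq
    witnesses: list[tuple[str, str]] = field(default_factory=list)
    locus: str | None = None

    @property
    def signature(self) -> tuple:
        return (
            self.event_type,
            self.region.chrom,
            self.region.start,
            self.region.end,
            self.inclusion_form,
            self.exclusion_form,
        )


@dataclass(frozen=True)
class APASite:
    gene: str
    chrom: str
    strand: str
    position: int
    support: int


def _site_roles(t: TranscriptModel) -> SiteSeq:
    """Splice sites of one transcript with genomic roles: D = intron start."""
    sites: list[tuple[int, str]] = []
    for donor, acceptor in build_splice_chain(t).introns:
        sites.append((donor, "D"))
        sites.append((acceptor, "A"))
    return tuple(sites)


def _covered_by_exon(t: TranscriptModel, start: int, end: int) -> bool:
    return any(e.start <= start and end <= e.end for e in t.exons)


def _classify_bubble(
    left: int | None,
    right: int | None,
    inner_a: SiteSeq,
    inner_b: SiteSeq,
    a: TranscriptModel,
    b: TranscriptModel,
) -> tuple[str, tuple[int, int], SiteSeq, SiteSeq, tuple[str, str]] | None:
    """Classify one differing bubble.

    Returns (type, region, inclusion_form, exclusion_form,
    (inclusion_tid, exclusion_tid)) or None when the bubble carries no
    splice-structure difference (pure end difference).
    """
    if inner_a == inner_b:
        return None
    strand = a.strand
    chrom = a.chrom

    def roles(s: SiteSeq) -> tuple[str, ...]:
        return tuple(r for _, r in s)

    # ---- IR: intron in one, nothing in the other, intron inside an exon
    for intron_side, exon_side, sites in (
        (a, b, (inner_a, inner_b)),
        (b, a, (inner_b, inner_a)),
    ):
        s_intr, s_empty = sites
        if roles(s_intr) == ("D", "A") and not s_empty:
            d, ac = s_intr[0][0], s_intr[1][0]
            if _covered_by_exon(exon_side, d, ac):
                return (
                    "IR",
                    (d, ac),
                    (),  # inclusion: intron retained, no sites in region
                    s_intr,
                    (exon_side.id, intron_side.id),
                )

    # ---- ES / MXE: exon-shaped inner ('A','D')
    a_exonish = roles(inner_a) == ("A", "D")
    b_exonish = roles(inner_b) == ("A", "D")
    chain_a = set(build_splice_chain(a).introns)
    chain_b = set(build_splice_chain(b).introns)
    if left is not None and right is not None:
        if a_exonish and not inner_b and (left, right) in chain_b:
            s, e = inner_a[0][0], inner_a[1][0]
            return ("ES", (s, e), inner_a, (), (a.id, b.id))
        if b_exonish and not inner_a and (left, right) in chain_a:
            s, e = inner_b[0][0], inner_b[1][0]
            return ("ES", (s, e), inner_b, (), (b.id, a.id))
        if a_exonish and b_exonish:
            s1, e1 = inner_a[0][0], inner_a[1][0]
            s2, e2 = inner_b[0][0], inner_b[1][0]
            if e1 <= s2 or e2 <= s1:  # non-overlapping alternative exons
                first, second = (
                    ((inner_a, a.id), (inner_b, b.id))
                    if s1 < s2
                    else ((inner_b, b.id), (inner_a, a.id))
                )
                return (
                    "MXE",
                    (min(s1, s2), max(e1, e2)),
                    first[0],
                    second[0],
                    (first[1], second[1]),
                )

    # ---- A5SS / A3SS: single site each, same role, different position
    if len(inner_a) == 1 and len(inner_b) == 1 and roles(inner_a) == roles(inner_b):
        (pa, role), (pb, _) = inner_a[0], inner_b[0]
        if pa != pb:
            # role D: genomic-left intron boundary differs.  On '+' that is
            # the biological 5' (donor) site; on '-' it is the 3' site.
            if role == "D":
                etype = "A5SS" if strand == "+" else "A3SS"
                # the transcript with the *larger* donor keeps more exon
                incl, excl = (
                    ((inner_a, a.id), (inner_b, b.id))
                    if pa > pb
                    else ((inner_b, b.id), (inner_a, a.id))
                )
            else:
                etype = "A3SS" if strand == "+" else "A5SS"
                incl, excl = (
                    ((inner_a, a.id), (inner_b, b.id))
                    if pa < pb
                    else ((inner_b, b.id), (inner_a, a.id))
                )
            return (
                etype,
                (min(pa, pb), max(pa, pb)),
                incl[0],
                excl[0],
                (incl[1], excl[1]),
            )

    # ---- anything else: complex (multi-site rearrangement)
    positions = [p for p, _ in inner_a + inner_b]
    lo, hi = min(positions), max(positions)
    if hi == lo:
        hi = lo + 1
    forms = sorted((inner_a, inner_b))
    tids = (a.id, b.id) if (inner_a, inner_b) == (forms[0], forms[1]) else (b.id, a.id)
    return ("complex", (lo, hi), forms[0], forms[1], tids)


def detect_pairwise_events(
    a: TranscriptModel, b: TranscriptModel, locus: str | None = None
) -> list[ASEvent]:
    """All typed AS events distinguishing two isoforms of one locus."""
    if a.chrom != b.chrom or a.strand != b.strand:
        raise StrandMismatchError(
            f"transcripts {a.id} and {b.id} are not comparable "
            "(different chromosome or strand)"
        )
    sites_a, sites_b = _site_roles(a), _site_roles(b)
    anchors = sorted(set(sites_a) & set(sites_b))
    anchor_pos = [p for p, _ in anchors]

    bounds: list[tuple[int | None, int | None]] = []
    prev: int | None = None
    for p in anchor_pos:
        bounds.append((prev, p))
        prev = p
    bounds.append((prev, None))

    events: list[ASEvent] = []
    for left, right in bounds:
        def _inner(sites: SiteSeq) -> SiteSeq:
            return tuple(
                (p, r)
                for p, r in sites
                if (left is None or p > left) and (right is None or p < right)
            )

        res = _classify_bubble(left, right, _inner(sites_a), _inner(sites_b), a, b)
        if res is None:
            continue
        etype, (lo, hi), incl, excl, pair = res
        events.append(
            ASEvent(
                event_type=etype,
                region=GenomicInterval(a.chrom, lo, hi, a.strand),
                inclusion_form=incl,
                exclusion_form=excl,
                witnesses=[pair],
                locus=locus,
            )
        )
    return events


def detect_locus_events(
    ts: Sequence[TranscriptModel], locus: str | None = None
) -> list[ASEvent]:
    """Union of pairwise events over a locus, structurally deduplicated."""
    if len({(t.chrom, t.strand) for t in ts}) > 1:
        raise StrandMismatchError("locus transcripts span multiple chrom/strands")
    merged: dict[tuple, ASEvent] = {}
    ordered = sorted(ts, key=lambda t: t.id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            for ev in detect_pairwise_events(a, b, locus=locus):
                sig = ev.signature
                if sig in merged:
                    merged[sig].witnesses.extend(ev.witnesses)
                else:
                    merged[sig] = ev
    out = sorted(
        merged.values(), key=lambda e: (e.region.start, e.region.end, e.event_type)
    )
    return out


def count_events_by_type(events: Iterable[ASEvent]) -> dict[str, int]:
    """Event counts per canonical type; ``complex`` tallied separately."""
    counts = {t: 0 for t in EVENT_TYPES}
    counts["complex"] = 0
    for ev in events:
        counts[ev.event_type] += 1
    return counts


# ---------------------------------------------------------------------------
# APA


def call_polya_sites(
    ends: Iterable[tuple[str, str, str, int]],
    window: int = 24,
    min_support: int = 2,
) -> list[APASite]:
    """Cluster read 3'-end positions into supported poly(A) sites.

    ``ends`` yields ``(gene, chrom, strand, position)`` records (one per
    FLNC read).  Per gene, positions cluster by single linkage with gap
    <= ``window``; clusters of size >= ``min_support`` are reported at their
    modal position (ties resolved toward the most 3' position given the
    strand).
    """
    per_gene: dict[str, tuple[str, str, list[int]]] = {}
    for gene, chrom, strand, pos in ends:
        if gene in per_gene:
            per_gene[gene][2].append(pos)
        else:
            per_gene[gene] = (chrom, strand, [pos])

    sites: list[APASite] = []
    for gene in sorted(per_gene):
        chrom, strand, positions = per_gene[gene]
        positions.sort()
        clusters: list[list[int]] = []
        for pos in positions:
            if clusters and pos - clusters[-1][-1] <= window:
                clusters[-1].append(pos)
            else:
                clusters.append([pos])
        for cluster in clusters:
            if len(cluster) < min_support:
                continue
            counts = Counter(cluster)
            top = max(counts.values())
            modal = [p for p, c in counts.items() if c == top]
            rep = max(modal) if strand == "+" else min(modal)
            sites.append(
                APASite(
                    gene=gene,
                    chrom=chrom,
                    strand=strand,
                    position=rep,
                    support=len(cluster),
                )
            )
    return sites


def apa_gene_distribution(
    sites_per_gene: Mapping[str, int]
) -> tuple[dict[str, int], float]:
    """Histogram of poly(A) sites per gene and the percentage of APA genes.

    Bins are 1,2,3,4,5,>5; the APA fraction is the percentage of genes with
    at least two sites among genes with at least one, half-up rounded to two
    decimals.
    """
    hist = {"1": 0, "2": 0, "3": 0, "4": 0, "5": 0, ">5": 0}
    multi = 0
    total = 0
    for gene, n in sites_per_gene.items():
        if n < 1:
            raise ValueError(f"gene {gene} has no sites; omit it instead")
        total += 1
        if n >= 2:
            multi += 1
        hist[str(n) if n <= 5 else ">5"] += 1
    if total == 0:
        return hist, 0.0
    frac = Decimal(100 * multi) / Decimal(total)
    return hist, float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
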