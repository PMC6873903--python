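"""Core genomic data model: intervals, transcript models, splice chains, loci.

All coordinates are 0-based half-open on the forward genomic strand.
GTF/GFF readers and writers (``isoseqtk.gtfio``) convert to and from the
1-based inclusive convention; nothing outside the I/O layer ever sees
1-based coordinates.

The central identity key for isoform comparison is the *splice chain*: the
ordered list of intron ``(donor, acceptor)`` coordinate pairs in genomic
orientation.  "Donor" here means the genomic-left intron boundary (the exon
end) and "acceptor" the genomic-right boundary (the next exon start),
regardless of strand; the biological donor/acceptor roles are resolved via
the strand where they matter (alternative 5'/3' splice-site typing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-")


class StrandMismatchError(ValueError):
    """Raised when an operation is asked to compare features on different strands."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (strand-agnostic queries only).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Edge-to-edge gap in bp; 0 if the intervals overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class SpliceChain:
    """Ordered intron list of one transcript; empty for single-exon models."""

    introns: tuple[tuple[int, int], ...]
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = -1
        for donor, acceptor in self.introns:
            if donor >= acceptor:
                raise ValueError(f"invalid intron ({donor},{acceptor})")
            if donor <= prev_end:
                raise ValueError("introns must be sorted and non-overlapping")
            prev_end = acceptor

    def __len__(self) -> int:
        return len(self.introns)

    def sites(self) -> tuple[int, ...]:
        """All splice-site coordinates (donors and acceptors), flattened."""
        return tuple(c for intron in self.introns for c in intron)


@dataclass
class TranscriptModel:
    """One isoform on the genome as an ordered exon chain."""

    id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"transcript {self.id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.id}: no exons")
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        merged: list[GenomicInterval] = []
        for exon in self.exons:
            if exon.chrom != self.chrom:
                raise ValueError(f"transcript {self.id}: exon on wrong chromosome")
            if merged and exon.start <= merged[-1].end:
                if exon.start < merged[-1].end:
                    raise ValueError(f"transcript {self.id}: overlapping exons")
                # zero-length gap: degenerate annotation, merge into one exon
                merged[-1] = GenomicInterval(
                    self.chrom, merged[-1].start, exon.end, self.strand
                )
            else:
                merged.append(
                    GenomicInterval(self.chrom, exon.start, exon.end, self.strand)
                )
        self.exons = tuple(merged)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    def three_prime_end(self) -> int:
        """Genomic coordinate of the 3' terminus (strand-aware)."""
        return self.end if self.strand == "+" else self.start

    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end

    def exonic_overlap_bp(self, other: "TranscriptModel") -> int:
        """Total exon-exon overlap in bp between two transcripts."""
        if self.chrom != other.chrom:
            return 0
        total = 0
        for a in self.exons:
            for b in other.exons:
                total += a.overlap_bp(b)
        return total


def build_splice_chain(t: TranscriptModel) -> SpliceChain:
    """The ordered intron (donor, acceptor) list of a transcript.

    A single-exon transcript yields an empty chain.
    """
    introns = tuple(
        (a.end, b.start) for a, b in zip(t.exons, t.exons[1:])
    )
    return SpliceChain(introns=introns, strand=t.strand)


def exons_from_chain(
    chrom: str, span: tuple[int, int], chain: SpliceChain
) -> tuple[GenomicInterval, ...]:
    """Reconstruct the exon list of a transcript from its span and splice chain.

    Inverse of :func:`build_splice_chain` given the transcript span; used for
    round-trip checks and for rebuilding merged models.
    """
    start, end = span
    bounds = [start]
    for donor, acceptor in chain.introns:
        bounds.extend((donor, acceptor))
    bounds.append(end)
    return tuple(
        GenomicInterval(chrom, s, e, chain.strand)
        for s, e in zip(bounds[::2], bounds[1::2])
    )


def shared_splice_sites(a: SpliceChain, b: SpliceChain) -> int:
    """Number of splice-site coordinates occurring in both chains.

    A position counts once whether it appears as a donor or an acceptor.
    Symmetric; comparing a chain against itself returns twice its intron
    count.  Chains on different strands are incomparable.
    """
    if a.strand != b.strand:
        raise StrandMismatchError(
            f"cannot compare splice chains on strands {a.strand!r} and {b.strand!r}"
        )
    return len(set(a.sites()) & set(b.sites()))


@dataclass
class GeneLocus:
    """A gene locus: a genomic span grouping one or more transcript models."""

    id: str
    span: GenomicInterval
    transcripts: list[str] = field(default_factory=list)
    origin: str = "reference"  # or "novel"

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand


class AnnotationIndex:
    """Indexed view over an annotation: loci, transcripts, splice sites.

    Supports fast overlap queries by chromosome (interval tree per chrom)
    and exposes per-locus splice-site sets used by transcript classification.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.loci: dict[str, GeneLocus] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._chains: dict[str, SpliceChain] = {}
        self._locus_sites: dict[str, set[int]] = {}

        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            if t.id in self.transcripts:
                raise ValueError(f"duplicate transcript id {t.id}")
            self.transcripts[t.id] = t
            self._chains[t.id] = build_splice_chain(t)
            gene = t.gene_id if t.gene_id is not None else t.id
            by_gene.setdefault(gene, []).append(t)

        for gene_id, members in sorted(by_gene.items()):
            chroms = {t.chrom for t in members}
            strands = {t.strand for t in members}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValueError(
                    f"gene {gene_id}: member transcripts disagree on chrom/strand"
                )
            span = GenomicInterval(
                members[0].chrom,
                min(t.start for t in members),
                max(t.end for t in members),
                members[0].strand,
            )
            locus = GeneLocus(
                id=gene_id,
                span=span,
                transcripts=sorted(t.id for t in members),
            )
            self.loci[gene_id] = locus
            self._locus_sites[gene_id] = {
                s for t in members for s in self._chains[t.id].sites()
            }
            tree = self._trees.setdefault(span.chrom, IntervalTree())
            tree.addi(span.start, span.end, gene_id)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[GeneLocus]:
        return iter(self.loci.values())

    def chain(self, transcript_id: str) -> SpliceChain:
        return self._chains[transcript_id]

    def locus_splice_sites(self, locus_id: str) -> set[int]:
        return self._locus_sites[locus_id]

    def locus_transcripts(self, locus_id: str) -> list[TranscriptModel]:
        return [self.transcripts[tid] for tid in self.loci[locus_id].transcripts]

    def overlapping_loci(
        self, query: GenomicInterval, same_strand: bool = False
    ) -> list[GeneLocus]:
        """All loci whose span intersects ``query`` (optionally strand-matched)."""
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = [self.loci[iv.data] for iv in tree.overlap(query.start, query.end)]
        if same_strand and query.strand in STRANDS:
            hits = [l for l in hits if l.strand == query.strand]
        return sorted(hits, key=lambda l: (l.span.start, l.id))


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint."""
    ov = a.overlap_bp(b)
    if ov == 0:
        return 0.0
    return min(ov / len(a), ov / len(b))
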