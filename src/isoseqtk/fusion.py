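"""Fusion transcript detection from multi-locus alignments of single reads.

A read is called a fusion transcript when its complete alignment set
satisfies all four criteria:

A. it maps to two or more loci;
B. each locus hit covers at least ``min_locus_fraction`` (5%) of the read
   and at least ``min_locus_bp`` aligned bases;
C. the hits together cover at least ``min_total_fraction`` (95%) of the read;
D. same-chromosome hits are at least ``min_gap`` (10 kb) apart, measured
   between the nearest span edges (distance across chromosomes is
   undefined, so D never excludes inter-chromosomal candidates).

Hits whose spans overlap are merged into one locus before the criteria are
applied, so a split alignment within a single gene is not miscalled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import GenomicInterval


@dataclass(frozen=True)
class LocusHit:
    """One alignment hit of a read against one genomic locus."""

    chrom: str
    strand: str
    span: GenomicInterval
    read_fraction: float
    covered_bp: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.read_fraction <= 1.0):
            raise ValueError("read_fraction must be in [0,1]")
        if self.read_fraction > 0 and self.covered_bp < 1:
            raise ValueError("covered_bp must be >= 1 for a non-empty hit")


@dataclass(frozen=True)
class FusionParams:
    min_locus_fraction: float = 0.05
    min_locus_bp: int = 1
    min_total_fraction: float = 0.95
    min_gap: int = 10_000


@dataclass(frozen=True)
class FusionCall:
    read_id: str
    hits: tuple[LocusHit, ...]
    total_fraction: float
    scope: str  # intra_chromosomal | inter_chromosomal


def _merge_overlapping_hits(hits: Sequence[LocusHit]) -> list[LocusHit]:
    """Merge hits whose spans overlap (same chrom) into single locus hits."""
    ordered = sorted(hits, key=lambda h: (h.chrom, h.span.start, h.span.end))
    merged: list[LocusHit] = []
    for h in ordered:
        if (
            merged
            and merged[-1].chrom == h.chrom
            and h.span.start < merged[-1].span.end
        ):
            prev = merged[-1]
            merged[-1] = LocusHit(
                chrom=prev.chrom,
                strand=prev.strand,
                span=GenomicInterval(
                    prev.chrom,
                    prev.span.start,
                    max(prev.span.end, h.span.end),
                    prev.span.strand,
                ),
                read_fraction=min(1.0, prev.read_fraction + h.read_fraction),
                covered_bp=prev.covered_bp + h.covered_bp,
            )
        else:
            merged.append(h)
    return merged


def detect_fusion(
    read_id: str, hits: Sequence[LocusHit], params: FusionParams | None = None
) -> FusionCall | None:
    """Apply the fusion criteria to the complete hit set of one read."""
    if not hits:
        raise ValueError(f"read {read_id}: empty hit list")
    if params is None:
        params = FusionParams()

    merged = _merge_overlapping_hits(hits)
    if len(merged) < 2:  # criterion A
        return None
    for h in merged:  # criterion B
        if h.read_fraction < params.min_locus_fraction or h.covered_bp < params.min_locus_bp:
            return None
    total = sum(h.read_fraction for h in merged)
    if total < params.min_total_fraction:  # criterion C
        return None
    for i, a in enumerate(merged):  # criterion D (same-chromosome pairs only)
        for b in merged[i + 1 :]:
            if a.chrom == b.chrom and a.span.gap_to(b.span) < params.min_gap:
                return None

    chroms = {h.chrom for h in merged}
    scope = "intra_chromosomal" if len(chroms) == 1 else "inter_chromosomal"
    return FusionCall(
        read_id=read_id, hits=tuple(merged), total_fraction=total, scope=scope
    )


def detect_fusions(
    hits_by_read: dict[str, Sequence[LocusHit]],
    params: FusionParams | None = None,
) -> list[FusionCall]:
    calls = []
    for read_id in sorted(hits_by_read):
        call = detect_fusion(read_id, hits_by_read[read_id], params)
        if call is not None:
            calls.append(call)
    return calls


def fusion_scope_summary(calls: Iterable[FusionCall]) -> dict[str, int]:
    summary = {"intra": 0, "inter": 0}
    for call in calls:
        summary["intra" if call.scope == "intra_chromosomal" else "inter"] += 1
    return summary
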