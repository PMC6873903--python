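"""Microsatellite (SSR) scanning with MISA-style rules.

A simple sequence repeat is a maximal perfect tandem repeat of a primitive
1-6 bp motif (a motif is primitive when it is not itself a repetition of a
shorter unit, so ``AA`` counts as a mononucleotide run, never a
dinucleotide).  Default minimum repeat numbers follow the MISA defaults:
mono 10, di 6, tri 5, tetra 5, penta 5, hexa 5.  Sequences shorter than
``min_seq_len`` (500 bp) are not scanned.  Two or more SSRs separated by at
most ``compound_gap`` (100 bp) merge into one compound record.  Non-ACGT
characters break repeat runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}
SSR_TYPES = ("p1", "p2", "p3", "p4", "p5", "p6", "compound")

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class SSRMotif:
    """One SSR: a perfect repeat ``(motif) x repeats`` or a compound record."""

    ssr_type: str  # p1..p6 | compound
    motif: str  # e.g. "(AG)7" or "(AG)7+(T)11" for compounds
    repeats: int  # unit count; for compounds, the number of member SSRs
    start: int  # 0-based, in sequence coordinates
    end: int  # exclusive
    transcript_id: str | None = None
    members: tuple["SSRMotif", ...] = ()


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def _perfect_repeats(seq: str, thresholds: Mapping[int, int]) -> list[SSRMotif]:
    """All maximal primitive perfect tandem repeats meeting the thresholds."""
    n = len(seq)
    found: list[SSRMotif] = []
    for k, min_reps in sorted(thresholds.items()):
        j = k
        while j < n:
            if (
                seq[j] == seq[j - k]
                and seq[j] in _ACGT
                and seq[j - k] in _ACGT
            ):
                run_start = j
                while j < n and seq[j] == seq[j - k] and seq[j] in _ACGT:
                    j += 1
                s = run_start - k
                total = (j - run_start) + k
                reps = total // k
                motif = seq[s : s + k]
                if reps >= min_reps and _is_primitive(motif):
                    found.append(
                        SSRMotif(
                            ssr_type=f"p{k}",
                            motif=f"({motif}){reps}",
                            repeats=reps,
                            start=s,
                            end=s + reps * k,
                        )
                    )
                j = max(j, run_start + 1)
            else:
                j += 1
    return found


def _resolve_overlaps(found: list[SSRMotif]) -> list[SSRMotif]:
    """Greedy keep-longest among overlapping SSRs (tie: smaller unit size)."""
    ranked = sorted(
        found, key=lambda m: (-(m.end - m.start), int(m.ssr_type[1]), m.start)
    )
    kept: list[SSRMotif] = []
    for m in ranked:
        if all(m.end <= o.start or o.end <= m.start for o in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept


def scan_ssr(
    seq: str,
    thresholds: Mapping[int, int] | None = None,
    min_seq_len: int = 500,
    compound_gap: int = 100,
    transcript_id: str | None = None,
) -> list[SSRMotif]:
    """Scan one sequence for SSRs; empty if shorter than ``min_seq_len``."""
    if len(seq) < min_seq_len:
        return []
    seq = seq.upper()
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    simple = _resolve_overlaps(_perfect_repeats(seq, thresholds))

    # merge runs of SSRs separated by <= compound_gap into compound records
    out: list[SSRMotif] = []
    group: list[SSRMotif] = []

    def _flush() -> None:
        if not group:
            return
        if len(group) == 1:
            m = group[0]
            out.append(
                SSRMotif(
                    ssr_type=m.ssr_type,
                    motif=m.motif,
                    repeats=m.repeats,
                    start=m.start,
                    end=m.end,
                    transcript_id=transcript_id,
                )
            )
        else:
            out.append(
                SSRMotif(
                    ssr_type="compound",
                    motif="+".join(m.motif for m in group),
                    repeats=len(group),
                    start=group[0].start,
                    end=group[-1].end,
                    transcript_id=transcript_id,
                    members=tuple(group),
                )
            )

    for m in simple:
        if group and m.start - group[-1].end <= compound_gap:
            group.append(m)
        else:
            _flush()
            group = [m]
    _flush()
    return out


def scan_transcripts(
    sequences: Mapping[str, str],
    thresholds: Mapping[int, int] | None = None,
    min_seq_len: int = 500,
    compound_gap: int = 100,
) -> list[SSRMotif]:
    """Scan a transcript id -> sequence mapping; deterministic order."""
    motifs: list[SSRMotif] = []
    for tid in sorted(sequences):
        motifs.extend(
            scan_ssr(
                sequences[tid],
                thresholds=thresholds,
                min_seq_len=min_seq_len,
                compound_gap=compound_gap,
                transcript_id=tid,
            )
        )
    return motifs


def ssr_density(
    motifs: Iterable[SSRMotif], scanned_bp: int
) -> dict[str, float]:
    """Motifs per megabase of scanned sequence, per SSR type."""
    if scanned_bp <= 0:
        raise ValueError("scanned_bp must be positive")
    density = {t: 0.0 for t in SSR_TYPES}
    for m in motifs:
        density[m.ssr_type] += 1
    return {t: c * 1_000_000 / scanned_bp for t, c in density.items()}


def write_misa_tsv(motifs: Sequence[SSRMotif], path) -> None:
    """MISA-style table: id, ssr_nr, type, motif, size, start, end (1-based)."""
    with open(path, "w") as fh:
        fh.write("ID\tSSR nr.\tSSR type\tSSR\tsize\tstart\tend\n")
        counter: dict[str, int] = {}
        for m in motifs:
            tid = m.transcript_id or "seq"
            counter[tid] = counter.get(tid, 0) + 1
            fh.write(
                f"{tid}\t{counter[tid]}\t{m.ssr_type}\t{m.motif}\t"
                f"{m.end - m.start}\t{m.start + 1}\t{m.end}\n"
            )
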