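"""Classification of consensus long reads (ROIs) from primer and poly(A) evidence.

A read of insert (ROI) is the error-corrected consensus of one sequencing
molecule.  In sense (cDNA) orientation a complete molecule reads::

    [5' primer] [transcript] [poly(A) tail] [3' primer]

Reads are classified into:

* ``subthreshold`` — shorter than 50 bp (discarded upstream in practice);
* ``short``        — shorter than the 300 bp filter;
* ``chimeric``     — a primer hit outside both end windows (artificial
  concatemer of two or more cDNA molecules);
* ``FLNC``         — full-length non-chimeric: 5' primer at the head, 3'
  primer at the tail, a poly(A) tail, and no internal primer;
* ``NFL``          — everything else (non-full-length).

Primer matching is semi-global (free end gaps on the read, computed with
edlib in infix mode) at a configurable identity threshold.  Both read
orientations are searched; the reported evidence refers to the better
(sense) orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import edlib
from Bio import SeqIO

SUBTHRESHOLD_LEN = 50
SHORT_LEN = 300

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ROIRecord:
    """One consensus read with its vendor quality metadata."""

    id: str
    sequence: str
    predicted_accuracy: float = 1.0
    passes: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.predicted_accuracy <= 1.0):
            raise ValueError("predicted_accuracy must be in [0,1]")
        if self.passes < 0:
            raise ValueError("passes must be >= 0")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerConfig:
    """Primer sequences and detection thresholds.

    ``end_window`` is how far from each read end a primer may sit and still
    count as terminal; matches anywhere else are concatemer evidence.
    """

    primer5: str
    primer3: str
    end_window: int = 100
    min_primer_identity: float = 0.8
    polya_min_len: int = 8
    polya_max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not self.primer5 or not self.primer3:
            raise ValueError("primers must be non-empty")
        if self.end_window < max(len(self.primer5), len(self.primer3)):
            raise ValueError("end_window must be >= the longest primer")


@dataclass(frozen=True)
class ROIClass:
    """Classification outcome with the evidence that produced it."""

    label: str  # FLNC | NFL | chimeric | short | subthreshold
    has5p: bool = False
    has3p: bool = False
    has_polya: bool = False
    internal_primer: bool = False
    polya_pos: int | None = None
    orientation: str = "+"  # "+" sense as given, "-" reverse-complemented


def _match_identity(primer: str, window: str) -> float:
    """Best semi-global identity of ``primer`` inside ``window`` (0 if none)."""
    if len(window) < 1:
        return 0.0
    res = edlib.align(primer.upper(), window.upper(), mode="HW", task="distance")
    if res["editDistance"] < 0:
        return 0.0
    return 1.0 - res["editDistance"] / len(primer)


def detect_polya(seq: str, cfg: PrimerConfig) -> int | None:
    """Start of the 3'-terminal poly(A) run, or ``None``.

    Any terminal 3' primer is trimmed first; the run must end at the
    (trimmed) 3' end, start on an A, span at least ``polya_min_len`` bases
    and contain at most ``polya_max_mismatch`` non-A bases.  The returned
    position is the leftmost valid run start, in coordinates of ``seq``.
    """
    if not seq:
        return None
    end = len(seq)
    tail = seq[-cfg.end_window :].upper()
    res = edlib.align(cfg.primer3.upper(), tail, mode="HW", task="locations")
    if res["editDistance"] >= 0 and (
        1.0 - res["editDistance"] / len(cfg.primer3) >= cfg.min_primer_identity
    ):
        loc_start = res["locations"][0][0]
        end = len(seq) - len(tail) + loc_start

    window_start = max(0, end - cfg.end_window)
    best: int | None = None
    mismatches = 0
    for p in range(end - 1, window_start - 1, -1):
        if seq[p].upper() != "A":
            mismatches += 1
            if mismatches > cfg.polya_max_mismatch:
                break
            continue
        if end - p >= cfg.polya_min_len:
            best = p
    return best


def _terminal_and_internal_evidence(
    seq: str, cfg: PrimerConfig
) -> tuple[bool, bool, bool]:
    """(has5p, has3p, internal_primer) for one fixed orientation."""
    head = seq[: cfg.end_window]
    tail = seq[-cfg.end_window :]
    has5p = _match_identity(cfg.primer5, head) >= cfg.min_primer_identity
    has3p = _match_identity(cfg.primer3, tail) >= cfg.min_primer_identity

    interior = seq[cfg.end_window : -cfg.end_window]
    internal = False
    for primer in (cfg.primer5, cfg.primer3):
        for probe in (primer, revcomp(primer)):
            if _match_identity(probe, interior) >= cfg.min_primer_identity:
                internal = True
                break
        if internal:
            break
    return has5p, has3p, internal


def classify_roi(roi: ROIRecord, cfg: PrimerConfig) -> ROIClass:
    """Classify one ROI; orientation-agnostic (both strands searched)."""
    n = roi.length
    if n < SUBTHRESHOLD_LEN:
        return ROIClass(label="subthreshold")
    if n < SHORT_LEN:
        return ROIClass(label="short")

    candidates = []
    for orientation, seq in (("+", roi.sequence), ("-", revcomp(roi.sequence))):
        has5p, has3p, internal = _terminal_and_internal_evidence(seq, cfg)
        polya = detect_polya(seq, cfg)
        score = int(has5p) + int(has3p) + int(polya is not None)
        candidates.append((score, orientation, has5p, has3p, internal, polya))
    # prefer the orientation with more full-length evidence; tie -> sense
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, orientation, has5p, has3p, internal, polya = candidates[0]

    if internal:
        label = "chimeric"
    elif has5p and has3p and polya is not None:
        label = "FLNC"
    else:
        label = "NFL"
    return ROIClass(
        label=label,
        has5p=has5p,
        has3p=has3p,
        has_polya=polya is not None,
        internal_primer=internal,
        polya_pos=polya,
        orientation=orientation,
    )


def classify_rois(
    rois: Iterable[ROIRecord], cfg: PrimerConfig
) -> dict[str, ROIClass]:
    return {roi.id: classify_roi(roi, cfg) for roi in rois}


def fl_percentage(n_fl: int, n_roi: int) -> float:
    """Full-length percentage, 100*n_fl/n_roi, half-up rounded to 2 decimals."""
    if n_roi <= 0:
        raise ValueError("n_roi must be positive")
    if n_fl > n_roi:
        raise ValueError("n_fl cannot exceed n_roi")
    pct = Decimal(100 * n_fl) / Decimal(n_roi)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def roi_passes_filter(
    roi: ROIRecord, min_passes: int = 0, min_accuracy: float = 0.75
) -> bool:
    """Vendor-style ROI pre-filter: full passes >= 0, predicted accuracy > 75%."""
    return roi.passes >= min_passes and roi.predicted_accuracy > min_accuracy


def read_fastx(path: str | Path) -> Iterator[ROIRecord]:
    """Read ROIs from FASTA or FASTQ (format chosen by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fq", ".fastq") else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield ROIRecord(id=rec.id, sequence=str(rec.seq))


def write_classification_tsv(
    classes: dict[str, ROIClass], lengths: dict[str, int], path: str | Path | TextIO
) -> None:
    handle = open(path, "w") if isinstance(path, (str, Path)) else path
    owned = isinstance(path, (str, Path))
    try:
        handle.write("read_id\tclass\thas5p\thas3p\tpolyA_pos\tlength\n")
        for rid in sorted(classes):
            c = classes[rid]
            handle.write(
                f"{rid}\t{c.label}\t{int(c.has5p)}\t{int(c.has3p)}\t"
                f"{c.polya_pos if c.polya_pos is not None else 'NA'}\t{lengths[rid]}\n"
            )
    finally:
        if owned:
            handle.close()
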