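"""Readers and writers for transcript models: GTF, GFF3 and BED12.

Internal coordinates are 0-based half-open; GTF/GFF3 use 1-based inclusive
and BED12 is already 0-based half-open, so only the GTF/GFF3 paths convert.
All writers round-trip losslessly through the matching reader.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .model import GenomicInterval, TranscriptModel

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]*)")


def _open(path: str | Path | TextIO, mode: str = "r"):
    if hasattr(path, "read") or hasattr(path, "write"):
        return path, False
    return open(path, mode), True


def _parse_attrs(field: str, fmt: str) -> dict[str, str]:
    pattern = _GTF_ATTR if fmt == "gtf" else _GFF3_ATTR
    return dict(pattern.findall(field))


def read_gtf(path: str | Path | TextIO) -> list[TranscriptModel]:
    """Read transcript models from GTF (exon features grouped by transcript_id)."""
    return _read_tabular_annotation(path, fmt="gtf")


def read_gff3(path: str | Path | TextIO) -> list[TranscriptModel]:
    """Read transcript models from GFF3 (exon features grouped by Parent)."""
    return _read_tabular_annotation(path, fmt="gff3")


def _read_tabular_annotation(
    path: str | Path | TextIO, fmt: str
) -> list[TranscriptModel]:
    handle, owned = _open(path)
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str | None]] = {}
    order: list[str] = []
    gene_of_feature: dict[str, str] = {}  # GFF3: mRNA ID -> gene Parent
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed {fmt} line: {line[:80]!r}")
            chrom, _, ftype, start, end, _, strand, _, attr_field = fields[:9]
            attrs = _parse_attrs(attr_field, fmt)
            if fmt == "gff3" and ftype in ("mRNA", "transcript", "lnc_RNA"):
                fid = attrs.get("ID")
                parent = attrs.get("Parent")
                if fid and parent:
                    gene_of_feature[fid] = parent
                continue
            if ftype != "exon":
                continue
            if fmt == "gtf":
                tid = attrs.get("transcript_id")
                gid = attrs.get("gene_id")
            else:
                tid = attrs.get("Parent") or attrs.get("ID")
                gid = None
            if tid is None:
                raise ValueError(f"exon without transcript identifier: {line[:80]!r}")
            iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
                meta[tid] = (chrom, strand, gid)
            exons[tid].append(iv)
    finally:
        if owned:
            handle.close()

    models = []
    for tid in order:
        chrom, strand, gid = meta[tid]
        if gid is None:
            gid = gene_of_feature.get(tid)
        models.append(
            TranscriptModel(
                id=tid, chrom=chrom, strand=strand, exons=tuple(exons[tid]), gene_id=gid
            )
        )
    return models


def write_gtf(
    models: Iterable[TranscriptModel],
    path: str | Path | TextIO,
    extra_attrs: dict[str, dict[str, str]] | None = None,
    source: str = "isoseqtk",
) -> None:
    """Write transcript models as GTF exon features.

    ``extra_attrs`` maps transcript id -> additional attribute key/values
    (e.g. classification category) appended to every exon line.
    """
    handle, owned = _open(path, "w")
    try:
        for t in models:
            gid = t.gene_id if t.gene_id is not None else t.id
            attrs = f'gene_id "{gid}"; transcript_id "{t.id}";'
            for key, val in (extra_attrs or {}).get(t.id, {}).items():
                attrs += f' {key} "{val}";'
            for exon in t.exons:
                handle.write(
                    "\t".join(
                        (
                            t.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )
    finally:
        if owned:
            handle.close()


def read_bed12(path: str | Path | TextIO) -> list[TranscriptModel]:
    """Read transcript models from BED12 (blocks become exons)."""
    handle, owned = _open(path)
    models = []
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}")
            chrom, chrom_start, _, name, _, strand = f[0], int(f[1]), f[2], f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"BED12 block count mismatch in {name}")
            exons = tuple(
                GenomicInterval(chrom, chrom_start + s, chrom_start + s + size, strand)
                for s, size in zip(starts, sizes)
            )
            models.append(
                TranscriptModel(id=name, chrom=chrom, strand=strand, exons=exons)
            )
    finally:
        if owned:
            handle.close()
    return models


def write_bed12(
    models: Iterable[TranscriptModel], path: str | Path | TextIO
) -> None:
    handle, owned = _open(path, "w")
    try:
        for t in models:
            sizes = ",".join(str(len(e)) for e in t.exons)
            starts = ",".join(str(e.start - t.start) for e in t.exons)
            handle.write(
                "\t".join(
                    (
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        t.id,
                        "0",
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0",
                        str(t.n_exons),
                        sizes,
                        starts,
                    )
                )
                + "\n"
            )
    finally:
        if owned:
            handle.close()
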