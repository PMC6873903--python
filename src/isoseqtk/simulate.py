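"""Deterministic synthetic genomes, annotations, reads and counts with truth.

The generator emulates the statistical structure of a long-read
transcriptome study so that every pipeline stage can be tested against a
machine-readable truth table:

* a small genome (2 x 500 kb by default) with well-separated multi-isoform
  gene models;
* one planted AS variant isoform per event (IR, ES, A5SS, A3SS, MXE) with
  the event's exact genomic region recorded;
* full-length reads carrying primers and poly(A) tails, plus planted
  non-full-length, chimeric, short and subthreshold reads, in mixed
  orientations;
* block-level read-to-genome alignments (including sub-threshold
  coverage/identity records that the collapse filter must drop);
* per-gene 3'-end observations forming supported and unsupported poly(A)
  site clusters;
* multi-locus fusion hit sets satisfying all fusion criteria, and
  near-misses violating exactly one criterion each;
* lncRNA models planted per positional category with a coding-potential
  verdict table;
* SSR motifs embedded in novel transcript sequences (the background is
  scrubbed of incidental repeats, so the planted truth is exhaustive);
* negative-binomial count matrices with planted differentially expressed
  transcripts and gene-level similar/opposite pattern pairs.

The same seed yields byte-identical outputs.  Each stage draws from its own
derived random stream, so adding a stage never perturbs earlier ones.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .collapse import ReadAlignment
from .expression import CountMatrix
from .fusion import LocusHit
from .gtfio import write_bed12, write_gtf
from .model import GenomicInterval, TranscriptModel
from .reads import ROIRecord, revcomp

PRIMER5 = "AAGCAGTGGTATCAACGCAGAGTAC"
PRIMER3 = "CGCAGGAACTGAGTCGGATCCACTA"

_BASES = "ACGT"

# planted SSR motif menu (all primitive, chosen not to cascade across types)
_SSR_MENU = {
    1: [("A", 12), ("T", 13), ("C", 11), ("G", 12)],
    2: [("AG", 7), ("AT", 7), ("TC", 8), ("CA", 6)],
    3: [("ATC", 6), ("AAG", 5), ("CTG", 6)],
    4: [("AAGG", 5), ("ATCG", 5), ("TTAC", 5)],
    5: [("AATCG", 5), ("CTTAG", 5)],
    6: [("AATCGG", 5), ("CTTAGG", 5)],
}


@dataclass
class SimulationPlan:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 1
    n_chroms: int = 2
    chrom_len: int = 500_000
    n_genes: int = 60
    n_single_exon_genes: int = 6
    n_novel_genes: int = 12  # withheld from the reference annotation
    event_counts: dict[str, int] = field(
        default_factory=lambda: {"IR": 6, "ES": 5, "A5SS": 4, "A3SS": 4, "MXE": 3}
    )
    # reads
    reads_per_isoform: tuple[int, int] = (8, 14)
    n_nfl_reads: int = 300
    n_chimeric_reads: int = 40
    n_short_reads: int = 80
    n_subthreshold_reads: int = 30
    n_lowquality_alignments: int = 30
    polya_len: tuple[int, int] = (18, 30)
    read_error_rate: float = 0.0
    max_truncation_frac: float = 0.3
    # APA
    n_apa_genes: int = 12
    apa_sites_range: tuple[int, int] = (2, 4)
    n_single_site_genes: int = 30
    apa_site_spacing: int = 80
    apa_jitter: int = 4
    # fusion
    n_intra_fusions: int = 3
    n_inter_fusions: int = 3
    # lncRNA
    lnc_per_category: int = 5
    # SSR
    ssr_counts: dict[str, int] = field(
        default_factory=lambda: {
            "p1": 5, "p2": 5, "p3": 3, "p4": 3, "p5": 2, "p6": 2, "compound": 3
        }
    )
    # DET / counts
    n_expr_transcripts: int = 200
    n_det: int = 40  # half up, half down
    n_pattern_genes: int = 6  # two-transcript genes; half similar, half opposite
    n_reps: int = 3
    nb_dispersion: float = 0.05
    det_log2fc: float = 2.0

    def validate(self) -> None:
        if any(v < 0 for v in self.event_counts.values()):
            raise ValueError("event counts must be non-negative")
        n_events = sum(self.event_counts.values())
        multi = self.n_genes - self.n_single_exon_genes
        if n_events > multi:
            raise ValueError(
                f"{n_events} planted events need {n_events} multi-exon host "
                f"genes, only {multi} available"
            )
        if self.n_novel_genes >= self.n_genes:
            raise ValueError("cannot withhold every gene from the reference")
        if 2 * self.n_pattern_genes > self.n_det:
            raise ValueError("pattern genes cannot outnumber planted DETs")
        if self.n_det > self.n_expr_transcripts:
            raise ValueError("too many planted DETs for the expression table")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        n_apa = self.n_apa_genes + self.n_single_site_genes + 5
        if n_apa > self.n_genes:
            raise ValueError("not enough genes for the APA plan")


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    single_exon: bool
    in_reference: bool
    isoforms: list[TranscriptModel] = field(default_factory=list)


@dataclass
class SimulationResult:
    plan: SimulationPlan
    genome: dict[str, str]
    genes: list[Gene]
    reference: list[TranscriptModel]
    isoforms: list[TranscriptModel]  # all true coding isoforms (base + variants)
    reads: list[ROIRecord]
    alignments: list[ReadAlignment]
    apa_ends: list[tuple[str, str, str, int]]
    fusion_hits: dict[str, list[LocusHit]]
    lnc_models: list[TranscriptModel]
    verdicts: dict[str, dict[str, str]]
    ssr_sequences: dict[str, str]
    counts: CountMatrix
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_gtf(self.reference, outdir / "reference.gtf")
        write_gtf(self.isoforms, outdir / "isoforms_truth.gtf")
        write_gtf(self.lnc_models, outdir / "lnc_candidates.gtf")
        with open(outdir / "reads.fasta", "w") as fh:
            for roi in self.reads:
                fh.write(f">{roi.id}\n{roi.sequence}\n")
        write_bed12(
            [a.to_transcript() for a in self.alignments], outdir / "alignments.bed"
        )
        with open(outdir / "alignments.tsv", "w") as fh:
            fh.write("read_id\tchrom\tstrand\tblocks\tcoverage\tidentity\n")
            for a in self.alignments:
                blocks = ",".join(f"{b.start}-{b.end}" for b in a.blocks)
                fh.write(
                    f"{a.read_id}\t{a.chrom}\t{a.strand}\t{blocks}\t"
                    f"{a.read_coverage:.4f}\t{a.identity:.4f}\n"
                )
        with open(outdir / "apa_ends.tsv", "w") as fh:
            fh.write("gene\tchrom\tstrand\tposition\n")
            for gene, chrom, strand, pos in self.apa_ends:
                fh.write(f"{gene}\t{chrom}\t{strand}\t{pos}\n")
        with open(outdir / "fusion_hits.tsv", "w") as fh:
            fh.write(
                "read_id\tchrom\tstrand\tstart\tend\tread_fraction\tcovered_bp\n"
            )
            for rid in sorted(self.fusion_hits):
                for h in self.fusion_hits[rid]:
                    fh.write(
                        f"{rid}\t{h.chrom}\t{h.strand}\t{h.span.start}\t"
                        f"{h.span.end}\t{h.read_fraction:.4f}\t{h.covered_bp}\n"
                    )
        with open(outdir / "verdicts.tsv", "w") as fh:
            fh.write("transcript_id\tcpc\tcnci\tcpat\tpfam\n")
            for tid in sorted(self.verdicts):
                v = self.verdicts[tid]
                fh.write(
                    f"{tid}\t{v['CPC']}\t{v['CNCI']}\t{v['CPAT']}\t{v['PFAM']}\n"
                )
        with open(outdir / "transcripts.fa", "w") as fh:
            for tid in sorted(self.ssr_sequences):
                fh.write(f">{tid}\n{self.ssr_sequences[tid]}\n")
        self.counts.counts.to_csv(outdir / "counts.tsv", sep="\t")
        with open(outdir / "design.tsv", "w") as fh:
            fh.write("sample\tcondition\n")
            for s in self.counts.counts.columns:
                fh.write(f"{s}\t{self.counts.condition[s]}\n")
        with open(outdir / "lengths.tsv", "w") as fh:
            fh.write("transcript_id\tgene_id\tlength\n")
            for tid in self.counts.counts.index:
                fh.write(
                    f"{tid}\t{self.counts.gene_of[tid]}\t{self.counts.lengths[tid]}\n"
                )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# helpers


def _rng(plan: SimulationPlan, stage: int) -> np.random.Generator:
    return np.random.default_rng((plan.seed, stage))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


_SANITIZE_PATTERNS = [
    re.compile(r"(.)\1{4,}"),  # mono runs >= 5
] + [re.compile(r"(.{%d})\1{2,}" % k) for k in range(2, 7)]  # >= 3 units


def _sanitize(seq: list[str], rng: np.random.Generator) -> None:
    """Break tandem repeats in-place so the background carries no SSRs."""
    for _ in range(10):
        text = "".join(seq)
        dirty = False
        for pat in _SANITIZE_PATTERNS:
            for m in pat.finditer(text):
                mid = (m.start() + m.end()) // 2
                old = seq[mid]
                choices = [b for b in _BASES if b != old]
                seq[mid] = choices[int(rng.integers(0, len(choices)))]
                dirty = True
        if not dirty:
            return


def _spliced(genome: dict[str, str], t: TranscriptModel) -> str:
    s = "".join(genome[t.chrom][e.start : e.end] for e in t.exons)
    return s if t.strand == "+" else revcomp(s)


def _exons_to_model(
    tid: str, gene: Gene, exons: list[tuple[int, int]]
) -> TranscriptModel:
    return TranscriptModel(
        id=tid,
        chrom=gene.chrom,
        strand=gene.strand,
        exons=tuple(
            GenomicInterval(gene.chrom, s, e, gene.strand) for s, e in exons
        ),
        gene_id=gene.id,
    )


# ---------------------------------------------------------------------------
# gene and event construction


def _build_genes(plan: SimulationPlan, rng: np.random.Generator) -> list[Gene]:
    single_idx = set(
        np.linspace(0, plan.n_genes - 1, plan.n_single_exon_genes, dtype=int).tolist()
    )
    multi_idx = [i for i in range(plan.n_genes) if i not in single_idx]
    # novel genes: two single-exon plus multi-exon genes spread along the genome
    novel_idx = set(sorted(single_idx)[:2])
    stride = max(1, len(multi_idx) // max(1, plan.n_novel_genes - 2))
    for i in multi_idx[2::stride]:
        if len(novel_idx) >= plan.n_novel_genes:
            break
        novel_idx.add(i)
    for i in multi_idx:
        if len(novel_idx) >= plan.n_novel_genes:
            break
        novel_idx.add(i)

    genes: list[Gene] = []
    cursors = {f"chr{i + 1}": 15_000 for i in range(plan.n_chroms)}
    chroms = sorted(cursors)
    for g in range(plan.n_genes):
        chrom = chroms[g % plan.n_chroms]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        start = cursors[chrom]
        if g in single_idx:
            exon_len = int(rng.integers(420, 700))
            exons = [(start, start + exon_len)]
        else:
            n_exons = int(rng.integers(4, 7))
            exons = []
            pos = start
            for i in range(n_exons):
                elen = int(rng.integers(150, 220))
                exons.append((pos, pos + elen))
                pos += elen
                if i < n_exons - 1:
                    # one roomy intron per gene (hosts MXE exons / intronic lncRNAs)
                    ilen = (
                        int(rng.integers(900, 1200))
                        if i == 1
                        else int(rng.integers(260, 520))
                    )
                    pos += ilen
        end = exons[-1][1]
        cursors[chrom] = end + 9_000 + int(rng.integers(0, 1200))
        if cursors[chrom] > plan.chrom_len - 10_000:
            raise ValueError("chromosomes too short for the requested gene count")
        genes.append(
            Gene(
                id=f"G{g + 1:04d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                single_exon=g in single_idx,
                in_reference=g not in novel_idx,
            )
        )
    return genes


def _plant_events(
    plan: SimulationPlan, genes: list[Gene], rng: np.random.Generator
) -> list[dict]:
    """Create one variant isoform per planted event; return the event truth."""
    events: list[dict] = []
    hosts = [g for g in genes if not g.single_exon]
    order = list(rng.permutation(len(hosts)))
    slots = iter(order)

    for g in genes:
        g.isoforms.append(_exons_to_model(f"{g.id}.1", g, list(g.exons)))

    for etype in sorted(plan.event_counts):
        for _ in range(plan.event_counts[etype]):
            gene = hosts[next(slots)]
            exons = list(gene.exons)
            n = len(exons)
            if etype == "IR":
                i = int(rng.integers(1, n - 2))  # retain an interior intron
                region = (exons[i][1], exons[i + 1][0])
                var = exons[:i] + [(exons[i][0], exons[i + 1][1])] + exons[i + 2 :]
            elif etype == "ES":
                i = int(rng.integers(1, n - 1))  # skip an interior exon
                region = exons[i]
                var = exons[:i] + exons[i + 1 :]
            elif etype in ("A5SS", "A3SS"):
                i = int(rng.integers(0, n - 1))  # alter one boundary of intron i
                delta = int(rng.integers(30, 60))
                donor_side = (gene.strand == "+") == (etype == "A5SS")
                var = list(exons)
                if donor_side:  # genomic-left intron boundary (end of exon i)
                    old = exons[i][1]
                    new = old - delta
                    var[i] = (exons[i][0], new)
                else:  # genomic-right boundary (start of exon i+1)
                    old = exons[i + 1][0]
                    new = old + delta
                    var[i + 1] = (new, exons[i + 1][1])
                region = (min(old, new), max(old, new))
            elif etype == "MXE":
                # swap exon 1 for an alternative exon inside the roomy intron
                i = 1
                alt_len = int(rng.integers(90, 140))
                pad = int(rng.integers(60, 120))
                if exons[i][1] + pad + alt_len + 60 >= exons[i + 1][0]:
                    raise ValueError("intron too small to host an MXE exon")
                alt = (exons[i][1] + pad, exons[i][1] + pad + alt_len)
                var = exons[:i] + [alt] + exons[i + 1 :]
                region = (exons[i][0], alt[1])
            else:
                raise ValueError(f"unknown event type {etype}")

            tid = f"{gene.id}.{len(gene.isoforms) + 1}"
            gene.isoforms.append(_exons_to_model(tid, gene, var))
            events.append(
                {
                    "type": etype,
                    "chrom": gene.chrom,
                    "start": int(region[0]),
                    "end": int(region[1]),
                    "gene": gene.id,
                }
            )
    return events


def _plant_lncrnas(
    plan: SimulationPlan, genes: list[Gene], rng: np.random.Generator
) -> tuple[list[TranscriptModel], dict[str, str]]:
    """lncRNA models per positional category (relative to reference genes)."""
    ref_genes = [g for g in genes if g.in_reference and not g.single_exon]
    order = list(rng.permutation(len(ref_genes)))
    models: list[TranscriptModel] = []
    truth: dict[str, str] = {}
    k = 0

    def _two_exon(chrom, strand, start, e1, gap, e2, tid):
        return TranscriptModel(
            id=tid,
            chrom=chrom,
            strand=strand,
            exons=(
                GenomicInterval(chrom, start, start + e1, strand),
                GenomicInterval(
                    chrom, start + e1 + gap, start + e1 + gap + e2, strand
                ),
            ),
        )

    for cat in ("lincRNA", "intronic", "antisense", "sense"):
        for j in range(plan.lnc_per_category):
            gene = ref_genes[order[k % len(order)]]
            k += 1
            tid = f"LNC_{cat}_{j + 1}"
            gene_start = gene.exons[0][0]
            if cat == "lincRNA":
                # inside the intergenic gap upstream of the gene
                start = gene_start - 6_000 - j * 37
                m = _two_exon(gene.chrom, "+", start, 160, 180, 150, tid)
            elif cat == "intronic":
                # inside the roomy intron (between exons 1 and 2), either strand
                istart, iend = gene.exons[1][1], gene.exons[2][0]
                start = istart + 40
                e1, e2 = 120, 110
                gap = (iend - 60) - (start + e1) - e2
                strand = "+" if j % 2 == 0 else "-"
                m = _two_exon(gene.chrom, strand, start, e1, gap, e2, tid)
            elif cat == "antisense":
                strand = "-" if gene.strand == "+" else "+"
                m = _two_exon(gene.chrom, strand, gene_start + 20, 140, 200, 140, tid)
            else:  # sense
                m = _two_exon(
                    gene.chrom, gene.strand, gene_start + 10, 150, 220, 150, tid
                )
            models.append(m)
            truth[tid] = cat
    return models, truth


# ---------------------------------------------------------------------------
# reads


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    n_mut = rng.binomial(len(chars), rate)
    for pos in rng.choice(len(chars), size=n_mut, replace=False):
        old = chars[pos]
        choices = [b for b in _BASES if b != old]
        chars[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def _make_reads_and_alignments(
    plan: SimulationPlan,
    genome: dict[str, str],
    isoforms: list[TranscriptModel],
    rng: np.random.Generator,
) -> tuple[list[ROIRecord], dict[str, str], list[ReadAlignment], dict]:
    reads: list[ROIRecord] = []
    labels: dict[str, str] = {}
    alignments: list[ReadAlignment] = []
    collapse_truth: dict[str, list[str]] = {}
    counter = 0

    def _emit(seq: str, label: str) -> str:
        nonlocal counter
        counter += 1
        rid = f"roi_{counter:05d}"
        seq = _mutate(seq, plan.read_error_rate, rng)
        if counter % 2 == 0:
            seq = revcomp(seq)
        reads.append(ROIRecord(id=rid, sequence=seq))
        labels[rid] = label
        return rid

    def _tail() -> str:
        return "A" * int(rng.integers(plan.polya_len[0], plan.polya_len[1] + 1))

    # FLNC reads: sampled per isoform with 5' truncation inside the first exon
    for iso in isoforms:
        n_reads = int(rng.integers(*plan.reads_per_isoform))
        members: list[str] = []
        for _ in range(n_reads):
            exons = [[e.start, e.end] for e in iso.exons]
            first = 0 if iso.strand == "+" else len(exons) - 1
            exon_len = exons[first][1] - exons[first][0]
            max_trunc = max(
                0,
                min(
                    int(plan.max_truncation_frac * iso.exonic_length), exon_len - 30
                ),
            )
            trunc = int(rng.integers(0, max_trunc + 1)) if max_trunc > 0 else 0
            if iso.strand == "+":
                exons[0][0] += trunc
            else:
                exons[-1][1] -= trunc
            model = TranscriptModel(
                id="tmp",
                chrom=iso.chrom,
                strand=iso.strand,
                exons=tuple(
                    GenomicInterval(iso.chrom, s, e, iso.strand) for s, e in exons
                ),
            )
            cdna = _spliced(genome, model)
            rid = _emit(PRIMER5 + cdna + _tail() + PRIMER3, "FLNC")
            members.append(rid)
            alignments.append(
                ReadAlignment(
                    read_id=rid,
                    chrom=iso.chrom,
                    strand=iso.strand,
                    blocks=model.exons,
                    read_coverage=1.0,
                    identity=1.0,
                )
            )
        collapse_truth[iso.id] = sorted(members)

    # NFL: missing 5' primer or missing poly(A)
    for i in range(plan.n_nfl_reads):
        iso = isoforms[int(rng.integers(0, len(isoforms)))]
        cdna = _spliced(genome, iso)
        if i % 2 == 0:
            seq = cdna + _tail() + PRIMER3  # no 5' primer
        else:
            # no poly(A); make sure the cDNA terminus cannot mimic a tail
            if cdna[-10:].count("A") > 7:
                cdna = cdna[:-2] + "CG"
            seq = PRIMER5 + cdna + PRIMER3
        _emit(seq, "NFL")

    # chimeric: artificial concatemers with internal primers
    for _ in range(plan.n_chimeric_reads):
        a = isoforms[int(rng.integers(0, len(isoforms)))]
        b = isoforms[int(rng.integers(0, len(isoforms)))]
        seq = (
            PRIMER5
            + _spliced(genome, a)
            + _tail()
            + PRIMER3
            + PRIMER5
            + _spliced(genome, b)
            + _tail()
            + PRIMER3
        )
        _emit(seq, "chimeric")

    # short (< 300 bp) and subthreshold (< 50 bp)
    for _ in range(plan.n_short_reads):
        iso = isoforms[int(rng.integers(0, len(isoforms)))]
        cdna = _spliced(genome, iso)
        frag_len = int(rng.integers(60, 200))
        start = int(rng.integers(0, max(1, len(cdna) - frag_len)))
        _emit(PRIMER5 + cdna[start : start + frag_len] + PRIMER3, "short")
    for _ in range(plan.n_subthreshold_reads):
        _emit(_random_seq(rng, int(rng.integers(20, 46))), "subthreshold")

    # low-quality alignments the collapse filter must drop
    dropped = []
    for i in range(plan.n_lowquality_alignments):
        iso = isoforms[int(rng.integers(0, len(isoforms)))]
        rid = f"lowq_{i + 1:03d}"
        cov, ident = (0.70, 0.95) if i % 2 == 0 else (0.95, 0.85)
        alignments.append(
            ReadAlignment(
                read_id=rid,
                chrom=iso.chrom,
                strand=iso.strand,
                blocks=iso.exons,
                read_coverage=cov,
                identity=ident,
            )
        )
        dropped.append(rid)

    truth = {"collapse_members": collapse_truth, "dropped_alignments": dropped}
    return reads, labels, alignments, truth


# ---------------------------------------------------------------------------
# APA, fusion, SSR, counts


def _plant_apa(
    plan: SimulationPlan, genes: list[Gene], rng: np.random.Generator
) -> tuple[list[tuple[str, str, str, int]], dict]:
    ends: list[tuple[str, str, str, int]] = []
    truth_sites: dict[str, list[int]] = {}
    apa_genes = genes[: plan.n_apa_genes]
    single_genes = genes[
        plan.n_apa_genes : plan.n_apa_genes + plan.n_single_site_genes
    ]
    noise_genes = genes[
        plan.n_apa_genes
        + plan.n_single_site_genes : plan.n_apa_genes
        + plan.n_single_site_genes
        + 5
    ]

    def _site_positions(gene: Gene, k: int) -> list[int]:
        base = gene.exons[-1][1] if gene.strand == "+" else gene.exons[0][0]
        sign = 1 if gene.strand == "+" else -1
        return [base + sign * (i * plan.apa_site_spacing) for i in range(k)]

    def _add_cluster(gene: Gene, s: int) -> None:
        # modal anchor twice, then distinct small jitters (mode stays unique)
        support = int(rng.integers(2, 6))
        ends.append((gene.id, gene.chrom, gene.strand, s))
        ends.append((gene.id, gene.chrom, gene.strand, s))
        for j in range(support - 2):
            ends.append((gene.id, gene.chrom, gene.strand, s + j + 1))

    for gene in apa_genes:
        k = int(rng.integers(plan.apa_sites_range[0], plan.apa_sites_range[1] + 1))
        sites = _site_positions(gene, k)
        truth_sites[gene.id] = sorted(sites)
        for s in sites:
            _add_cluster(gene, s)
    for gene in single_genes:
        s = _site_positions(gene, 1)[0]
        truth_sites[gene.id] = [s]
        _add_cluster(gene, s)
    noise = []
    for gene in noise_genes:  # support-1 clusters: must be discarded
        s = _site_positions(gene, 1)[0]
        ends.append((gene.id, gene.chrom, gene.strand, s))
        noise.append(gene.id)
    rng.shuffle(ends)  # input order must not matter
    return ends, {
        "sites": {g: s for g, s in sorted(truth_sites.items())},
        "unsupported_genes": sorted(noise),
    }


def _plant_fusions(
    plan: SimulationPlan, genes: list[Gene], rng: np.random.Generator
) -> tuple[dict[str, list[LocusHit]], dict]:
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    chroms = sorted(by_chrom)

    def _hit(gene: Gene, frac: float, read_len: int = 1500) -> LocusHit:
        span = GenomicInterval(
            gene.chrom, gene.exons[0][0], gene.exons[-1][1], gene.strand
        )
        return LocusHit(
            chrom=gene.chrom,
            strand=gene.strand,
            span=span,
            read_fraction=frac,
            covered_bp=max(1, int(frac * read_len)),
        )

    hits: dict[str, list[LocusHit]] = {}
    accepted, rejected = [], []
    k = 0
    for i in range(plan.n_intra_fusions):
        pool = by_chrom[chroms[i % len(chroms)]]
        a, b = pool[2 * i], pool[2 * i + 3]  # three gene slots apart (>> 10 kb)
        rid = f"fusion_{k + 1:03d}"
        k += 1
        hits[rid] = [_hit(a, 0.49), _hit(b, 0.48)]
        accepted.append([rid, "intra"])
    for i in range(plan.n_inter_fusions):
        a = by_chrom[chroms[0]][10 + i]
        b = by_chrom[chroms[-1]][10 + i]
        rid = f"fusion_{k + 1:03d}"
        k += 1
        hits[rid] = [_hit(a, 0.50), _hit(b, 0.47)]
        accepted.append([rid, "inter"])

    # near-misses: each violates exactly one criterion
    pool = by_chrom[chroms[0]]
    far_a, far_b = pool[0], pool[5]
    # A: both hits inside one locus (overlapping spans are merged first)
    span = GenomicInterval(
        far_a.chrom, far_a.exons[0][0], far_a.exons[-1][1], far_a.strand
    )
    half = GenomicInterval(
        far_a.chrom, span.start, (span.start + span.end) // 2 + 1, far_a.strand
    )
    hits["miss_A"] = [
        LocusHit(far_a.chrom, far_a.strand, span, 0.50, 700),
        LocusHit(far_a.chrom, far_a.strand, half, 0.48, 700),
    ]
    # B: one locus below the 5% floor
    hits["miss_B"] = [_hit(far_a, 0.93), _hit(far_b, 0.04)]
    # C: total coverage below 95%
    hits["miss_C"] = [_hit(far_a, 0.50), _hit(far_b, 0.42)]
    # D: same-chromosome loci closer than 10 kb
    g = pool[7]
    near_span = GenomicInterval(
        g.chrom, g.exons[-1][1] + 5_000, g.exons[-1][1] + 5_800, g.strand
    )
    hits["miss_D"] = [_hit(g, 0.49), LocusHit(g.chrom, g.strand, near_span, 0.48, 700)]
    rejected = ["miss_A", "miss_B", "miss_C", "miss_D"]

    return hits, {"accepted": sorted(accepted), "rejected": sorted(rejected)}


def _plant_ssrs(
    plan: SimulationPlan,
    genome: dict[str, list[str]],
    isoforms: list[TranscriptModel],
    categories: dict[str, str],
    rng: np.random.Generator,
) -> tuple[list[dict], set[tuple[str, int]]]:
    """Embed SSR motifs into exon 1 of novel transcripts.

    The genome is modified in place.  One host per gene (sibling isoforms
    share exons, so a planted run surfaces in every transcript containing
    the host exon — the truth table is computed afterwards by projection,
    see :func:`_ssr_truth`).  Returns (planted run groups, protected genome
    positions).
    """
    # one host transcript per gene; the planted run goes into the largest
    # exon at offset 65, so sibling isoforms with shifted exon boundaries
    # (alternative splice-site variants move a boundary by < 60 bp) either
    # contain the run completely or not at all — never a partial repeat
    hosts = []
    seen_genes: set[str] = set()
    for t in sorted(
        (
            t
            for t in isoforms
            if categories[t.id] != "known_isoform"
            and t.exonic_length >= 520
            and max(len(e) for e in t.exons) >= 180
        ),
        key=lambda t: t.id,
    ):
        gene = t.gene_id or t.id
        if gene not in seen_genes:
            seen_genes.add(gene)
            hosts.append(t)
    rng.shuffle(hosts)
    planted: list[dict] = []
    protected: set[tuple[str, int]] = set()
    menu_idx = {k: 0 for k in _SSR_MENU}
    host_i = 0

    def _pick(k: int) -> tuple[str, int]:
        motif, reps = _SSR_MENU[k][menu_idx[k] % len(_SSR_MENU[k])]
        menu_idx[k] += 1
        return motif, reps

    def _plant_run(t: TranscriptModel, offset: int, motif: str, reps: int) -> dict:
        exon = max(t.exons, key=lambda e: (len(e), -e.start))
        gstart = exon.start + offset
        run = motif * reps
        seq = genome[t.chrom]
        for j, ch in enumerate(run):
            seq[gstart + j] = ch
        # enforce maximality: neither flank may extend the repeat
        if seq[gstart - 1] == motif[-1]:
            seq[gstart - 1] = next(
                b for b in _BASES if b != motif[-1] and b != motif[0]
            )
        endpos = gstart + len(run)
        if seq[endpos] == motif[0]:
            seq[endpos] = next(b for b in _BASES if b != motif[0] and b != motif[-1])
        protected.update((t.chrom, p) for p in range(gstart - 1, endpos + 1))
        return {
            "chrom": t.chrom,
            "start": gstart,
            "end": endpos,
            "k": len(motif),
            "motif": motif,
            "reps": reps,
        }

    items: list[str] = []
    for stype in sorted(plan.ssr_counts):
        items.extend([stype] * plan.ssr_counts[stype])

    for stype in items:
        if host_i >= len(hosts):
            raise ValueError("not enough novel transcripts to host planted SSRs")
        t = hosts[host_i]
        host_i += 1
        if stype != "compound":
            k = int(stype[1])
            motif, reps = _pick(k)
            planted.append({"compound": False, "runs": [_plant_run(t, 65, motif, reps)]})
        else:
            m1, r1 = _pick(2)
            m2, r2 = _pick(1)
            start1 = 65
            run1 = _plant_run(t, start1, m1, r1)
            run2 = _plant_run(t, start1 + len(m1) * r1 + 12, m2, r2)
            planted.append({"compound": True, "runs": [run1, run2]})
    return planted, protected


def _ssr_truth(
    planted: list[dict], models: list[TranscriptModel]
) -> dict[str, list[dict]]:
    """Project planted runs onto every scanned transcript containing them.

    Motifs are reported in transcript orientation ('-' strand hosts carry
    the reverse-complement motif, and compound member order flips).
    """
    truth: dict[str, list[dict]] = {}
    for t in models:
        recs = []
        for group in planted:
            contained = all(
                any(
                    e.start < run["start"] and run["end"] < e.end
                    for e in t.exons
                )
                for run in group["runs"]
                if run["chrom"] == t.chrom
            ) and all(run["chrom"] == t.chrom for run in group["runs"])
            if not contained:
                continue

            def _member(run: dict) -> dict:
                motif = run["motif"] if t.strand == "+" else revcomp(run["motif"])
                return {"type": f"p{run['k']}", "motif": motif, "reps": run["reps"]}

            if group["compound"]:
                members = [_member(r) for r in group["runs"]]
                if t.strand == "-":
                    members.reverse()
                recs.append({"type": "compound", "members": members})
            else:
                recs.append(_member(group["runs"][0]))
        if recs:
            truth[t.id] = recs
    return truth


_SSR_ORACLE = [
    (k, re.compile(r"(.{%d})\1{%d,}" % (k, thr - 1)))
    for k, thr in ((1, 10), (2, 6), (3, 5), (4, 5), (5, 5), (6, 5))
]


def _scrub_transcript_seqs(
    genome: dict[str, list[str]],
    models: list[TranscriptModel],
    protected: set[tuple[str, int]],
    rng: np.random.Generator,
) -> None:
    """Break incidental SSRs in spliced transcript sequences (junction effects)."""
    genome_str = {c: "".join(s) for c, s in genome.items()}
    for _ in range(50):
        dirty = False
        for t in models:
            seq = _spliced(genome_str, t)
            for k, pat in _SSR_ORACLE:
                for m in pat.finditer(seq):
                    # map a transcript position back to the genome and break it
                    tpos = (m.start() + m.end()) // 2
                    if t.strand == "-":
                        tpos = len(seq) - 1 - tpos
                    acc = 0
                    gpos = None
                    for e in t.exons:
                        if tpos < acc + len(e):
                            gpos = e.start + (tpos - acc)
                            break
                        acc += len(e)
                    if gpos is None or (t.chrom, gpos) in protected:
                        continue
                    old = genome[t.chrom][gpos]
                    choices = [b for b in _BASES if b != old]
                    genome[t.chrom][gpos] = choices[int(rng.integers(0, 3))]
                    dirty = True
        if not dirty:
            return
        genome_str = {c: "".join(s) for c, s in genome.items()}


def nb_counts(plan: SimulationPlan) -> tuple[CountMatrix, dict]:
    """Negative-binomial count matrix with planted DETs and pattern genes."""
    rng = _rng(plan, 7)
    n = plan.n_expr_transcripts
    tids = [f"tx{i + 1:04d}" for i in range(n)]

    # the first 2*n_pattern_genes transcripts pair up into two-isoform genes
    gene_of: dict[str, str] = {}
    for i, tid in enumerate(tids):
        if i < 2 * plan.n_pattern_genes:
            gene_of[tid] = f"gene_p{i // 2 + 1:03d}"
        else:
            gene_of[tid] = f"gene_{i + 1:04d}"

    lengths = {t: int(l) for t, l in zip(tids, rng.integers(500, 3000, size=n))}
    base_mean = np.exp(rng.normal(4.5, 0.8, size=n))

    lfc = np.zeros(n)
    for i in range(plan.n_pattern_genes):
        if i < plan.n_pattern_genes // 2:  # similar: both transcripts one sign
            s = 1.0 if i % 2 == 0 else -1.0
            signs = (s, s)
        else:  # opposite
            signs = (1.0, -1.0)
        lfc[2 * i] = signs[0] * plan.det_log2fc
        lfc[2 * i + 1] = signs[1] * plan.det_log2fc
    extra = plan.n_det - 2 * plan.n_pattern_genes
    for j in range(extra):
        idx = 2 * plan.n_pattern_genes + j
        lfc[idx] = plan.det_log2fc if j % 2 == 0 else -plan.det_log2fc

    det_truth = {
        tid: ("up" if lfc[i] > 0 else "down")
        for i, tid in enumerate(tids)
        if lfc[i] != 0
    }

    samples = [f"FW_{r + 1}" for r in range(plan.n_reps)] + [
        f"SW_{r + 1}" for r in range(plan.n_reps)
    ]
    condition = {s: s.split("_")[0] for s in samples}
    depth = rng.normal(1.0, 0.05, size=len(samples)).clip(0.8, 1.2)

    mat = np.zeros((n, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = base_mean * (2.0 ** lfc if condition[s] == "SW" else 1.0) * depth[j]
        if plan.nb_dispersion < 1e-6:
            mat[:, j] = rng.poisson(mu)
        else:
            r = 1.0 / plan.nb_dispersion
            p = r / (r + mu)
            mat[:, j] = rng.negative_binomial(r, p)

    cm = CountMatrix(
        counts=pd.DataFrame(mat, index=tids, columns=samples),
        condition=condition,
        gene_of=gene_of,
        lengths=lengths,
    )
    patterns = {}
    for i in range(plan.n_pattern_genes):
        gid = f"gene_p{i + 1:03d}"
        signs = {det_truth[tids[2 * i]], det_truth[tids[2 * i + 1]]}
        patterns[gid] = "similar" if len(signs) == 1 else "opposite"
    truth = {
        "det": det_truth,
        "planted_log2fc": {t: float(l) for t, l in zip(tids, lfc)},
        "patterns": patterns,
    }
    return cm, truth


# ---------------------------------------------------------------------------
# top level


def simulate(
    plan: SimulationPlan | None = None, outdir: str | Path | None = None
) -> SimulationResult:
    """Generate the full synthetic study; optionally write it to ``outdir``."""
    if plan is None:
        plan = SimulationPlan()
    plan.validate()

    genes = _build_genes(plan, _rng(plan, 1))
    event_truth = _plant_events(plan, genes, _rng(plan, 2))
    isoforms = [iso for g in genes for iso in g.isoforms]
    reference = [g.isoforms[0] for g in genes if g.in_reference]

    categories = {}
    for g in genes:
        for i, iso in enumerate(g.isoforms):
            if not g.in_reference:
                categories[iso.id] = "novel_gene"
            elif i == 0:
                categories[iso.id] = "known_isoform"
            else:
                categories[iso.id] = "novel_isoform_known_gene"

    # genome: random background, scrubbed of tandem repeats, SSRs planted
    grng = _rng(plan, 3)
    genome_mut = {
        f"chr{i + 1}": list(_random_seq(grng, plan.chrom_len))
        for i in range(plan.n_chroms)
    }
    for seq in genome_mut.values():
        _sanitize(seq, grng)

    ssr_rng = _rng(plan, 4)
    planted_ssrs, protected = _plant_ssrs(
        plan, genome_mut, isoforms, categories, ssr_rng
    )
    novel_models = [t for t in isoforms if categories[t.id] != "known_isoform"]
    _scrub_transcript_seqs(genome_mut, novel_models, protected, ssr_rng)
    genome = {c: "".join(s) for c, s in genome_mut.items()}
    ssr_truth = _ssr_truth(planted_ssrs, novel_models)

    ssr_sequences = {t.id: _spliced(genome, t) for t in novel_models}

    reads, read_labels, alignments, collapse_truth = _make_reads_and_alignments(
        plan, genome, isoforms, _rng(plan, 5)
    )
    apa_ends, apa_truth = _plant_apa(plan, genes, _rng(plan, 6))
    counts, det_truth = nb_counts(plan)
    fusion_hits, fusion_truth = _plant_fusions(plan, genes, _rng(plan, 8))
    lnc_models, lnc_truth = _plant_lncrnas(plan, genes, _rng(plan, 9))

    # coding-potential verdicts: lncRNAs all-noncoding; decoys partly coding
    verdicts: dict[str, dict[str, str]] = {}
    for m in lnc_models:
        verdicts[m.id] = {s: "noncoding" for s in ("CPC", "CNCI", "CPAT", "PFAM")}
    vrng = _rng(plan, 10)
    decoys = []
    for iso in isoforms[:20]:
        v = {s: "noncoding" for s in ("CPC", "CNCI", "CPAT", "PFAM")}
        src = ("CPC", "CNCI", "CPAT", "PFAM")[int(vrng.integers(0, 4))]
        v[src] = "coding"
        verdicts[iso.id] = v
        decoys.append(iso.id)

    truth = {
        "read_labels": read_labels,
        "isoform_categories": categories,
        "novel_gene_count": plan.n_novel_genes,
        "events": event_truth,
        "apa": apa_truth,
        "fusion": fusion_truth,
        "ssr": ssr_truth,
        "lnc_categories": lnc_truth,
        "verdict_decoys": sorted(decoys),
        **collapse_truth,
        "det": det_truth,
    }

    result = SimulationResult(
        plan=plan,
        genome=genome,
        genes=genes,
        reference=reference,
        isoforms=isoforms,
        reads=reads,
        alignments=alignments,
        apa_ends=apa_ends,
        fusion_hits=fusion_hits,
        lnc_models=lnc_models,
        verdicts=verdicts,
        ssr_sequences=ssr_sequences,
        counts=counts,
        truth=truth,
    )
    if outdir is not None:
        result.write(outdir)
    return result
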