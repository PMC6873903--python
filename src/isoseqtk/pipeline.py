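"""File-level pipeline orchestration: stage runners over on-disk inputs.

Each runner reads the tabular formats the simulator (or an external tool)
emits, executes one analysis stage, and writes a TSV next to the inputs.
``run_pipeline`` chains the stages in dependency order and produces the
summary report; reruns with identical inputs yield identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import collapse as clp
from . import expression as expr
from . import fusion as fus
from . import lncrna as lnc
from . import report as rpt
from . import splicing as spl
from . import ssr as ssrmod
from .gtfio import read_gtf, write_gtf
from .model import AnnotationIndex, GenomicInterval
from .reads import PrimerConfig, classify_rois, read_fastx, write_classification_tsv

log = logging.getLogger("isoseqtk")


def load_alignments_tsv(path: str | Path) -> list[clp.ReadAlignment]:
    df = pd.read_csv(path, sep="\t")
    alns = []
    for row in df.itertuples(index=False):
        blocks = tuple(
            GenomicInterval(row.chrom, int(b.split("-")[0]), int(b.split("-")[1]), row.strand)
            for b in str(row.blocks).split(",")
        )
        alns.append(
            clp.ReadAlignment(
                read_id=row.read_id,
                chrom=row.chrom,
                strand=row.strand,
                blocks=blocks,
                read_coverage=float(row.coverage),
                identity=float(row.identity),
            )
        )
    return alns


def load_fusion_hits_tsv(path: str | Path) -> dict[str, list[fus.LocusHit]]:
    df = pd.read_csv(path, sep="\t")
    hits: dict[str, list[fus.LocusHit]] = {}
    for row in df.itertuples(index=False):
        hits.setdefault(row.read_id, []).append(
            fus.LocusHit(
                chrom=row.chrom,
                strand=row.strand,
                span=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                read_fraction=float(row.read_fraction),
                covered_bp=int(row.covered_bp),
            )
        )
    return hits


def load_verdicts_tsv(path: str | Path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, str]] = {}
    for row in df.itertuples(index=False):
        out[row.transcript_id] = {
            "CPC": row.cpc, "CNCI": row.cnci, "CPAT": row.cpat, "PFAM": row.pfam
        }
    return out


def load_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def load_counts(
    counts_tsv: str | Path, design_tsv: str | Path, lengths_tsv: str | Path
) -> expr.CountMatrix:
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    design = pd.read_csv(design_tsv, sep="\t")
    lengths = pd.read_csv(lengths_tsv, sep="\t")
    return expr.CountMatrix(
        counts=counts,
        condition=dict(zip(design["sample"], design["condition"])),
        gene_of=dict(zip(lengths["transcript_id"], lengths["gene_id"])),
        lengths=dict(zip(lengths["transcript_id"], lengths["length"])),
    )


def run_pipeline(workdir: str | Path, primer5: str, primer3: str) -> dict:
    """Run every stage over a simulator-layout directory; return the report.

    Expects the file set :meth:`isoseqtk.simulate.SimulationResult.write`
    produces.  Writes per-stage TSVs plus ``report.json`` into ``workdir``.
    """
    workdir = Path(workdir)
    log.info("pipeline start in %s", workdir)

    # 1. read classification
    cfg = PrimerConfig(primer5=primer5, primer3=primer3)
    rois = list(read_fastx(workdir / "reads.fasta"))
    classes = classify_rois(rois, cfg)
    write_classification_tsv(
        classes, {r.id: r.length for r in rois}, workdir / "roi_classes.tsv"
    )
    roi_counts: dict[str, int] = {}
    for c in classes.values():
        roi_counts[c.label] = roi_counts.get(c.label, 0) + 1

    # 2. collapse + classification against the reference
    params = clp.CollapseParams()
    alns = clp.filter_alignments(load_alignments_tsv(workdir / "alignments.tsv"), params)
    members: dict[str, list[str]] = {}
    models = clp.collapse_isoforms(alns, params, member_registry=members)
    ann = AnnotationIndex(read_gtf(workdir / "reference.gtf"))
    cats = clp.classify_transcripts(models, ann)
    cat_counts = {c: 0 for c in clp.CATEGORIES}
    for cat in cats.values():
        cat_counts[cat.label] += 1
    write_gtf(
        models,
        workdir / "collapsed.gtf",
        extra_attrs={
            t.id: {
                "category": cats[t.id].label,
                "matched_locus": cats[t.id].matched_locus or "NA",
                "shared_sites": str(cats[t.id].shared_site_count),
                "member_reads": ",".join(members.get(t.id, [])),
            }
            for t in models
        },
    )
    novel = [t for t in models if cats[t.id].label == "novel_gene"]
    novel_loci = clp.cluster_novel_loci(novel)

    # 3. AS events per locus (matched reference locus or novel locus)
    by_locus: dict[str, list] = {}
    for t in models:
        locus = cats[t.id].matched_locus
        if locus is not None:
            by_locus.setdefault(locus, []).append(t)
    for locus in novel_loci:
        by_locus[locus.id] = [t for t in novel if t.id in set(locus.transcripts)]
    events = []
    for locus_id in sorted(by_locus):
        events.extend(spl.detect_locus_events(by_locus[locus_id], locus=locus_id))
    as_counts = spl.count_events_by_type(events)
    with open(workdir / "as_events.tsv", "w") as fh:
        fh.write("type\tlocus\tchrom\tstart\tend\twitnesses\n")
        for ev in events:
            wit = ";".join(f"{a}|{b}" for a, b in ev.witnesses)
            fh.write(
                f"{ev.event_type}\t{ev.locus}\t{ev.region.chrom}\t"
                f"{ev.region.start}\t{ev.region.end}\t{wit}\n"
            )

    # 4. APA
    ends_df = pd.read_csv(workdir / "apa_ends.tsv", sep="\t")
    ends = [
        (r.gene, r.chrom, r.strand, int(r.position))
        for r in ends_df.itertuples(index=False)
    ]
    sites = spl.call_polya_sites(ends)
    per_gene: dict[str, int] = {}
    for s in sites:
        per_gene[s.gene] = per_gene.get(s.gene, 0) + 1
    apa_hist, apa_frac = spl.apa_gene_distribution(per_gene)
    with open(workdir / "polya_sites.bed", "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.gene}\t"
                f"{s.support}\t{s.strand}\n"
            )

    # 5. fusion
    calls = fus.detect_fusions(load_fusion_hits_tsv(workdir / "fusion_hits.tsv"))
    scope = fus.fusion_scope_summary(calls)
    with open(workdir / "fusions.tsv", "w") as fh:
        fh.write("read_id\tscope\tn_loci\ttotal_fraction\n")
        for call in calls:
            fh.write(
                f"{call.read_id}\t{call.scope}\t{len(call.hits)}\t"
                f"{call.total_fraction:.4f}\n"
            )

    # 6. lncRNA
    lnc_input = read_gtf(workdir / "lnc_candidates.gtf")
    verdicts = load_verdicts_tsv(workdir / "verdicts.tsv")
    candidates = lnc.select_lnc_candidates(lnc_input, verdicts)
    lnc_cats = lnc.classify_lnc_positions(candidates, ann)
    lnc_counts: dict[str, int] = {}
    for cat in lnc_cats.values():
        lnc_counts[cat] = lnc_counts.get(cat, 0) + 1
    with open(workdir / "lncrna_classes.tsv", "w") as fh:
        fh.write("transcript_id\tcategory\n")
        for tid in sorted(lnc_cats):
            fh.write(f"{tid}\t{lnc_cats[tid]}\n")

    # 7. SSR over novel transcript sequences
    seqs = load_fasta(workdir / "transcripts.fa")
    motifs = ssrmod.scan_transcripts(seqs)
    scanned = sum(len(s) for s in seqs.values() if len(s) >= 500)
    ssr_counts: dict[str, int] = {}
    for m in motifs:
        ssr_counts[m.ssr_type] = ssr_counts.get(m.ssr_type, 0) + 1
    ssrmod.write_misa_tsv(motifs, workdir / "ssr.tsv")

    # 8. DET
    cm = load_counts(
        workdir / "counts.tsv", workdir / "design.tsv", workdir / "lengths.tsv"
    )
    det_results = expr.differential_expression(cm)
    det_dir = expr.det_counts(det_results)
    patterns = expr.group_gene_patterns(det_results)
    with open(workdir / "det.tsv", "w") as fh:
        fh.write("gene\ttranscript\tFDR\tlog2FC\tis_det\tdirection\n")
        for r in det_results:
            lfc = "NA" if r.log2fc is None else f"{r.log2fc:.4f}"
            fdr = "NA" if r.fdr is None else f"{r.fdr:.3e}"
            fh.write(
                f"{r.gene_id}\t{r.transcript_id}\t{fdr}\t{lfc}\t"
                f"{int(r.is_det)}\t{r.direction or 'NA'}\n"
            )
    with open(workdir / "det_patterns.tsv", "w") as fh:
        fh.write("gene\tpattern\ttranscripts\n")
        for p in patterns:
            fh.write(f"{p.gene_id}\t{p.pattern}\t{','.join(p.det_transcripts)}\n")

    report = rpt.summarize(
        roi_classes=roi_counts,
        transcript_categories=cat_counts,
        as_events=as_counts,
        apa_sites_per_gene=apa_hist,
        lnc_categories=lnc_counts,
        ssr_counts=ssr_counts,
        ssr_scanned_bp=scanned,
        fusion_scopes={"intra": scope["intra"], "inter": scope["inter"]},
        det_directions=det_dir,
    )
    report["apa_gene_percentage"] = apa_frac
    report["novel_loci"] = len(novel_loci)
    with open(workdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    log.info("pipeline done: %d models, %d AS events", len(models), len(events))
    return report
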