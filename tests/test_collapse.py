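import numpy as np
import pytest

from conftest import match_model_to_isoform
from isoseqtk.collapse import (
    CollapseParams,
    ReadAlignment,
    classify_transcript,
    cluster_novel_loci,
    collapse_isoforms,
    filter_alignments,
    isoform_distribution,
)
from isoseqtk.model import AnnotationIndex, GeneLocus, GenomicInterval, TranscriptModel, build_splice_chain


def aln(read_id, exons, strand="+", chrom="chr1", cov=1.0, ident=1.0):
    return ReadAlignment(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        blocks=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        read_coverage=cov,
        identity=ident,
    )


def model(tid, exons, strand="+", chrom="chr1", gene=None):
    return TranscriptModel(
        id=tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        gene_id=gene,
    )


class TestFilter:
    @pytest.mark.parametrize(
        "cov,ident,kept",
        [
            (0.90, 0.95, True),
            (0.85, 0.90, True),  # thresholds are inclusive
            (0.84, 0.95, False),
            (0.95, 0.89, False),
        ],
    )
    def test_coverage_and_identity_thresholds(self, cov, ident, kept):
        a = aln("r", [(0, 500)], cov=cov, ident=ident)
        assert (filter_alignments([a], CollapseParams()) == [a]) is kept


class TestCollapse:
    def test_identical_chains_merge_keeping_longest_five_prime_end(self):
        a = aln("r1", [(100, 200), (300, 400), (500, 600), (700, 800)])
        b = aln("r2", [(130, 200), (300, 400), (500, 600), (700, 800)])
        models = collapse_isoforms([a, b])
        assert len(models) == 1
        assert models[0].start == 100 and models[0].end == 800

    def test_differing_donor_site_keeps_two_models(self):
        a = aln("r1", [(100, 200), (300, 400)])
        b = aln("r2", [(100, 220), (300, 400)])
        assert len(collapse_isoforms([a, b])) == 2

    def test_three_prime_ends_beyond_tolerance_stay_separate(self):
        a = aln("r1", [(100, 200), (300, 400)])
        b = aln("r2", [(100, 200), (300, 700)])
        assert len(collapse_isoforms([a, b], CollapseParams(end_tolerance_3p=100))) == 2
        assert len(collapse_isoforms([a, b], CollapseParams(end_tolerance_3p=300))) == 1

    def test_reads_from_planted_isoforms_collapse_to_planted_chains(self):
        rng = np.random.default_rng(0)
        isoforms = [
            [(0, 100), (200, 300), (400, 500)],
            [(0, 100), (400, 500)],
            [(0, 150), (200, 300), (400, 500)],
            [(1000, 1100), (1300, 1500)],
            [(1000, 1100), (1350, 1500)],
            [(3000, 3600)],
            [(5000, 5200), (5400, 5600), (5800, 6100)],
        ]
        alns = []
        for k in range(50):
            exons = [list(e) for e in isoforms[int(rng.integers(0, 7))]]
            exons[0][0] += int(rng.integers(0, min(40, exons[0][1] - exons[0][0] - 10)))
            alns.append(aln(f"r{k}", [tuple(e) for e in exons]))
        models = collapse_isoforms(alns)
        got = {build_splice_chain(m).introns for m in models}
        planted = {
            build_splice_chain(model("x", e)).introns for e in isoforms
        }
        assert len(models) == 7
        assert got == planted

    def test_collapse_is_idempotent(self, sim):
        params = CollapseParams()
        alns = filter_alignments(sim.alignments, params)
        models = collapse_isoforms(alns, params)
        again = collapse_isoforms(
            [
                ReadAlignment(m.id, m.chrom, m.strand, m.exons, 1.0, 1.0)
                for m in models
            ],
            params,
        )
        assert [(m.chrom, m.strand, tuple((e.start, e.end) for e in m.exons)) for m in models] == [
            (m.chrom, m.strand, tuple((e.start, e.end) for e in m.exons)) for m in again
        ]

    def test_input_order_never_changes_the_output(self, sim):
        params = CollapseParams()
        alns = filter_alignments(sim.alignments, params)
        fwd = collapse_isoforms(alns, params)
        rev = collapse_isoforms(list(reversed(alns)), params)
        key = lambda m: (m.chrom, m.start, tuple((e.start, e.end) for e in m.exons))
        assert sorted(map(key, fwd)) == sorted(map(key, rev))


class TestClassify:
    @pytest.fixture()
    def ann(self):
        return AnnotationIndex(
            [
                model("ref1", [(100, 200), (300, 400), (500, 600)], gene="gA"),
                model("ref2", [(5000, 5500)], gene="gB", strand="-"),
            ]
        )

    def test_exact_chain_match_is_known_isoform(self, ann):
        t = model("q", [(120, 200), (300, 400), (500, 580)])
        assert classify_transcript(t, ann).label == "known_isoform"

    def test_shared_site_with_novel_site_is_novel_isoform(self, ann):
        t = model("q", [(120, 200), (350, 400), (500, 580)])
        c = classify_transcript(t, ann)
        assert c.label == "novel_isoform_known_gene"
        assert c.matched_locus == "gA" and c.shared_site_count >= 1

    def test_no_locus_overlap_is_novel_gene(self, ann):
        t = model("q", [(9000, 9100), (9300, 9400)])
        c = classify_transcript(t, ann)
        assert c.label == "novel_gene" and c.matched_locus is None

    def test_every_reference_transcript_classifies_as_known(self, sim):
        ann = AnnotationIndex(sim.reference)
        for t in sim.reference:
            assert classify_transcript(t, ann).label == "known_isoform", t.id

    def test_planted_categories_fully_recovered(self, sim):
        params = CollapseParams()
        models = collapse_isoforms(filter_alignments(sim.alignments, params), params)
        ann = AnnotationIndex(sim.reference)
        truth = sim.truth["isoform_categories"]
        for m in models:
            iso = match_model_to_isoform(m, sim.isoforms)
            assert iso is not None
            assert classify_transcript(m, ann).label == truth[iso.id], iso.id


class TestNovelLoci:
    def test_transitive_overlap_forms_one_locus(self):
        ts = [
            model("A", [(0, 100)]),
            model("B", [(50, 150)]),
            model("C", [(140, 240)]),
        ]
        loci = cluster_novel_loci(ts)
        assert len(loci) == 1 and sorted(loci[0].transcripts) == ["A", "B", "C"]

    def test_opposite_strands_never_cluster(self):
        ts = [model("A", [(0, 100)], strand="+"), model("B", [(0, 100)], strand="-")]
        assert len(cluster_novel_loci(ts)) == 2

    def test_singleton_input_is_one_locus(self):
        assert len(cluster_novel_loci([model("A", [(0, 100)])])) == 1

    def test_exonic_not_span_overlap_is_required(self):
        # spans overlap but exons interleave without touching
        ts = [
            model("A", [(0, 100), (500, 600)]),
            model("B", [(200, 300)]),
        ]
        assert len(cluster_novel_loci(ts)) == 2


class TestIsoformDistribution:
    def test_bins_partition_loci(self):
        loci = [
            GeneLocus(f"g{i}", GenomicInterval("chr1", 0, 10), [f"t{j}" for j in range(n)])
            for i, n in enumerate([1, 1, 2, 5, 7])
        ]
        hist = isoform_distribution(loci)
        assert hist == {"1": 2, "2": 1, "3": 0, "4": 0, ">=5": 2}
        assert sum(hist.values()) == len(loci)

    def test_empty_input_gives_zero_histogram(self):
        assert isoform_distribution([]) == {"1": 0, "2": 0, "3": 0, "4": 0, ">=5": 0}

    def test_histogram_matches_direct_recount(self, sim):
        from isoseqtk.model import AnnotationIndex

        ann = AnnotationIndex(sim.isoforms)
        hist = isoform_distribution(ann)
        recount = {}
        for locus in ann:
            n = len(locus.transcripts)
            key = str(n) if n < 5 else ">=5"
            recount[key] = recount.get(key, 0) + 1
        assert all(hist[k] == recount.get(k, 0) for k in hist)
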