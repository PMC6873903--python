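import pytest

from isoseqtk.model import GenomicInterval, StrandMismatchError, TranscriptModel
from isoseqtk.splicing import (
    apa_gene_distribution,
    call_polya_sites,
    count_events_by_type,
    detect_locus_events,
    detect_pairwise_events,
)


def model(tid, exons, strand="+", chrom="chr1"):
    return TranscriptModel(
        id=tid,
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


def regions(events, etype):
    return sorted(
        (e.region.start, e.region.end) for e in events if e.event_type == etype
    )


class TestPairwiseEvents:
    def test_intron_inside_exon_is_ir(self):
        a = model("a", [(0, 100), (200, 300)])
        b = model("b", [(0, 300)])
        ev = detect_pairwise_events(a, b)
        assert [e.event_type for e in ev] == ["IR"]
        assert (ev[0].region.start, ev[0].region.end) == (100, 200)

    def test_skipped_internal_exon_is_es(self):
        a = model("a", [(0, 100), (200, 250), (400, 500)])
        b = model("b", [(0, 100), (400, 500)])
        ev = detect_pairwise_events(a, b)
        assert [e.event_type for e in ev] == ["ES"]
        assert (ev[0].region.start, ev[0].region.end) == (200, 250)

    def test_alternative_donor_on_plus_strand_is_a5ss(self):
        a = model("a", [(0, 100), (200, 300)])
        b = model("b", [(0, 120), (200, 300)])
        ev = detect_pairwise_events(a, b)
        assert [e.event_type for e in ev] == ["A5SS"]
        assert (ev[0].region.start, ev[0].region.end) == (100, 120)

    def test_alternative_donor_on_minus_strand_is_a3ss(self):
        a = model("a", [(0, 100), (200, 300)], strand="-")
        b = model("b", [(0, 120), (200, 300)], strand="-")
        assert [e.event_type for e in detect_pairwise_events(a, b)] == ["A3SS"]

    def test_alternative_acceptor_on_plus_strand_is_a3ss(self):
        a = model("a", [(0, 100), (200, 300)])
        b = model("b", [(0, 100), (240, 300)])
        assert [e.event_type for e in detect_pairwise_events(a, b)] == ["A3SS"]

    def test_mutually_exclusive_exons(self):
        a = model("a", [(0, 100), (200, 250), (400, 500)])
        b = model("b", [(0, 100), (300, 350), (400, 500)])
        ev = detect_pairwise_events(a, b)
        assert [e.event_type for e in ev] == ["MXE"]
        assert (ev[0].region.start, ev[0].region.end) == (200, 350)

    def test_overlapping_alternative_exons_are_complex_not_mxe(self):
        a = model("a", [(0, 100), (200, 260), (400, 500)])
        b = model("b", [(0, 100), (240, 300), (400, 500)])
        assert [e.event_type for e in detect_pairwise_events(a, b)] == ["complex"]

    def test_identical_transcripts_have_no_events(self):
        a = model("a", [(0, 100), (200, 300)])
        b = model("b", [(10, 100), (200, 290)])  # pure end differences
        assert detect_pairwise_events(a, b) == []

    def test_pairwise_is_symmetric(self):
        pairs = [
            ([(0, 100), (200, 300)], [(0, 300)]),
            ([(0, 100), (200, 250), (400, 500)], [(0, 100), (400, 500)]),
            ([(0, 100), (200, 300)], [(0, 120), (200, 300)]),
            ([(0, 100), (200, 250), (400, 500)], [(0, 100), (300, 350), (400, 500)]),
        ]
        for ea, eb in pairs:
            fwd = detect_pairwise_events(model("a", ea), model("b", eb))
            rev = detect_pairwise_events(model("b", eb), model("a", ea))
            assert [e.signature for e in fwd] == [e.signature for e in rev]

    def test_strand_mismatch_is_an_error(self):
        with pytest.raises(StrandMismatchError):
            detect_pairwise_events(
                model("a", [(0, 100), (200, 300)]),
                model("b", [(0, 100), (200, 300)], strand="-"),
            )

    def test_strand_mirror_swaps_a5ss_and_a3ss(self, sim):
        # reflect all coordinates and flip the strand: A5SS<->A3SS,
        # IR/ES/MXE counts preserved
        genes = {}
        for iso in sim.isoforms:
            genes.setdefault(iso.gene_id, []).append(iso)
        fwd_counts = {"IR": 0, "ES": 0, "A3SS": 0, "A5SS": 0, "MXE": 0, "complex": 0}
        mir_counts = dict(fwd_counts)
        C = 10_000_000
        for g, members in genes.items():
            mirrored = [
                model(
                    t.id,
                    sorted((C - e.end, C - e.start) for e in t.exons),
                    strand="-" if t.strand == "+" else "+",
                    chrom=t.chrom,
                )
                for t in members
            ]
            for ev in detect_locus_events(members):
                fwd_counts[ev.event_type] += 1
            for ev in detect_locus_events(mirrored):
                mir_counts[ev.event_type] += 1
        assert fwd_counts["IR"] == mir_counts["IR"]
        assert fwd_counts["ES"] == mir_counts["ES"]
        assert fwd_counts["MXE"] == mir_counts["MXE"]
        assert fwd_counts["A5SS"] == mir_counts["A3SS"]
        assert fwd_counts["A3SS"] == mir_counts["A5SS"]


class TestLocusEvents:
    def test_shared_event_deduplicates_with_accumulated_witnesses(self):
        t1 = model("t1", [(0, 100), (200, 300)])
        t2 = model("t2", [(0, 300)])
        t3 = model("t3", [(0, 310)])
        ev = [e for e in detect_locus_events([t1, t2, t3]) if e.event_type == "IR"]
        assert len(ev) == 1
        assert len(ev[0].witnesses) == 2

    def test_single_transcript_locus_has_no_events(self):
        assert detect_locus_events([model("t", [(0, 100), (200, 300)])]) == []

    def test_planted_locus_events_exactly_recovered(self, sim):
        genes = {}
        for iso in sim.isoforms:
            genes.setdefault(iso.gene_id, []).append(iso)
        detected = []
        for g in sorted(genes):
            detected.extend(detect_locus_events(genes[g], locus=g))
        got = sorted(
            (e.event_type, e.region.chrom, e.region.start, e.region.end)
            for e in detected
        )
        planted = sorted(
            (e["type"], e["chrom"], e["start"], e["end"])
            for e in sim.truth["events"]
        )
        assert got == planted  # perfect precision and recall

    def test_event_regions_overlap_witnesses(self, sim):
        genes = {}
        for iso in sim.isoforms:
            genes.setdefault(iso.gene_id, []).append(iso)
        by_id = {t.id: t for t in sim.isoforms}
        for g, members in genes.items():
            for ev in detect_locus_events(members):
                for incl, excl in ev.witnesses:
                    for tid in (incl, excl):
                        t = by_id[tid]
                        assert t.start <= ev.region.end and ev.region.start <= t.end


class TestPolyASites:
    def test_one_cluster_with_support(self):
        sites = call_polya_sites(
            [("g", "chr1", "+", 1000), ("g", "chr1", "+", 1003), ("g", "chr1", "+", 1004)]
        )
        assert len(sites) == 1
        assert sites[0].support == 3
        assert sites[0].position in (1003, 1004)  # modal tie -> most 3'

    def test_single_read_cluster_is_discarded(self):
        assert call_polya_sites([("g", "chr1", "+", 1000)]) == []

    def test_two_supported_clusters_make_an_apa_gene(self):
        ends = [("g", "chr1", "+", p) for p in (1000, 1000, 2000, 2000)]
        sites = call_polya_sites(ends)
        assert [s.position for s in sites] == [1000, 2000]
        assert all(s.support == 2 for s in sites)

    def test_modal_tie_breaks_most_three_prime_per_strand(self):
        ends = [("g", "chr1", "+", 100), ("g", "chr1", "+", 110)]
        assert call_polya_sites(ends, window=24)[0].position == 110
        ends = [("g", "chr1", "-", 100), ("g", "chr1", "-", 110)]
        assert call_polya_sites(ends, window=24)[0].position == 100


class TestApaDistribution:
    def test_published_style_fraction(self):
        per_gene = {f"s{i}": 1 for i in range(5147)}
        per_gene.update({f"m{i}": 2 for i in range(1359)})
        hist, frac = apa_gene_distribution(per_gene)
        assert hist["1"] == 5147 and hist["2"] == 1359
        assert frac == 20.89

    def test_all_single_site_genes_fraction_zero(self):
        assert apa_gene_distribution({"a": 1, "b": 1})[1] == 0.0

    def test_histogram_matches_planted_site_counts(self, sim):
        sites = call_polya_sites(sim.apa_ends)
        per_gene = {}
        for s in sites:
            per_gene[s.gene] = per_gene.get(s.gene, 0) + 1
        hist, _ = apa_gene_distribution(per_gene)
        truth = {g: len(v) for g, v in sim.truth["apa"]["sites"].items()}
        expected = {"1": 0, "2": 0, "3": 0, "4": 0, "5": 0, ">5": 0}
        for n in truth.values():
            expected[str(n) if n <= 5 else ">5"] += 1
        assert hist == expected
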