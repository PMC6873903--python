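import re

import numpy as np

from isoseqtk.reads import revcomp
from isoseqtk.ssr import DEFAULT_THRESHOLDS, scan_ssr, scan_transcripts, ssr_density

PAD = "GACTTGCATGACTGCTAGATCGAATGCAGTC"  # repeat-free filler


def filler(n):
    return (PAD * (n // len(PAD) + 1))[:n]


def simple_records(motifs):
    """Flatten to (type, motif-with-count, start, end), expanding compounds."""
    out = []
    for m in motifs:
        if m.ssr_type == "compound":
            out.extend((x.ssr_type, x.motif, x.start, x.end) for x in m.members)
        else:
            out.append((m.ssr_type, m.motif, m.start, m.end))
    return sorted(out, key=lambda r: r[2])


def regex_oracle(seq, thresholds=DEFAULT_THRESHOLDS):
    """Backtracking regex reference for maximal primitive perfect repeats."""
    found = []
    for k, thr in thresholds.items():
        for m in re.finditer(r"(.{%d})\1{%d,}" % (k, thr - 1), seq):
            unit = m.group(1)
            if any(c not in "ACGT" for c in unit):
                continue
            if any(
                len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d)
                for d in range(1, len(unit))
            ):
                continue  # motif not primitive
            reps = len(m.group(0)) // k
            found.append((f"p{k}", f"({unit}){reps}", m.start(), m.start() + reps * k))
    # longest-wins overlap resolution (tie: smaller unit)
    found.sort(key=lambda r: (-(r[3] - r[2]), int(r[0][1]), r[2]))
    kept = []
    for r in found:
        if all(r[3] <= o[2] or o[3] <= r[2] for o in kept):
            kept.append(r)
    return sorted(kept, key=lambda r: r[2])


class TestScanSsr:
    def test_mono_run_detected(self):
        seq = filler(300) + "A" * 12 + filler(300)
        motifs = scan_ssr(seq)
        assert [(m.ssr_type, m.motif) for m in motifs] == [("p1", "(A)12")]
        assert motifs[0].end - motifs[0].start == 12

    def test_dinucleotide_repeat_detected(self):
        seq = filler(300) + "AG" * 7 + filler(300)
        motifs = scan_ssr(seq)
        assert [(m.ssr_type, m.motif, m.repeats) for m in motifs] == [("p2", "(AG)7", 7)]

    def test_nearby_ssrs_merge_into_compound(self):
        seq = filler(300) + "AG" * 7 + filler(10) + "T" * 11 + filler(300)
        motifs = scan_ssr(seq)
        assert [m.ssr_type for m in motifs] == ["compound"]
        assert [x.motif for x in motifs[0].members] == ["(AG)7", "(T)11"]

    def test_distant_ssrs_stay_separate(self):
        seq = filler(300) + "AG" * 7 + filler(150) + "T" * 11 + filler(300)
        assert [m.ssr_type for m in scan_ssr(seq)] == ["p2", "p1"]

    def test_short_sequences_are_not_scanned(self):
        seq = filler(180) + "A" * 20 + filler(180)
        assert len(seq) < 500
        assert scan_ssr(seq) == []

    def test_mono_run_is_not_reported_as_dinucleotide(self):
        seq = filler(300) + "A" * 12 + filler(300)
        assert all(m.ssr_type != "p2" for m in scan_ssr(seq))

    def test_flanking_sequence_does_not_change_motifs(self):
        core = filler(250) + "ATC" * 6 + filler(250)
        base = simple_records(scan_ssr(core))
        padded = simple_records(scan_ssr(filler(100) + core + filler(100)))
        assert [(t, m) for t, m, *_ in base] == [(t, m) for t, m, *_ in padded]
        assert [s + 100 for _, _, s, _ in base] == [s for _, _, s, _ in padded]

    def test_reverse_complement_mirrors_motifs(self):
        # guard bases keep every run maximal on both sides, so the scan is
        # exactly mirror-symmetric
        seq = (
            filler(200) + "C" + "AAG" * 6 + "C" + filler(150)
            + "C" + "AT" * 7 + "C" + filler(260)
        )
        fwd = simple_records(scan_ssr(seq))
        rev = simple_records(scan_ssr(revcomp(seq)))
        n = len(seq)
        mirrored = sorted(
            [
                (
                    t,
                    f"({revcomp(m[1:].split(')')[0])}){m.split(')')[1]}",
                    n - e,
                    n - s,
                )
                for t, m, s, e in fwd
            ],
            key=lambda r: r[2],
        )
        assert rev == mirrored

    def test_reported_simple_ssrs_never_overlap(self, sim):
        for tid, seq in sim.ssr_sequences.items():
            recs = simple_records(scan_ssr(seq))
            for a, b in zip(recs, recs[1:]):
                assert a[3] <= b[2]


def test_agrees_with_regex_oracle_on_randomized_sequences():
    rng = np.random.default_rng(7)
    menu = ["A", "T", "AG", "CT", "ATC", "AAG", "AAGG", "AATCG", "AATCGG"]
    for trial in range(1000):
        pieces = [filler(int(rng.integers(120, 260)))]
        for _ in range(int(rng.integers(0, 4))):
            motif = menu[int(rng.integers(0, len(menu)))]
            reps = int(rng.integers(3, 15))
            pieces.append(motif * reps)
            pieces.append(filler(int(rng.integers(5, 160))))
        pieces.append(filler(200))
        seq = "".join(pieces)
        got = simple_records(scan_ssr(seq, min_seq_len=0))
        expected = [(t, m, s, e) for t, m, s, e in regex_oracle(seq)]
        assert got == expected, f"trial {trial}"


def test_density_per_megabase():
    seq = filler(300) + "A" * 12 + filler(300)
    motifs = scan_ssr(seq)
    d = ssr_density(motifs, 2_000_000)
    assert d["p1"] == 0.5
    assert all(v == 0.0 for t, v in d.items() if t != "p1")


def test_planted_motifs_exactly_recovered(sim):
    motifs = scan_transcripts(sim.ssr_sequences)
    got = {}
    for m in motifs:
        if m.ssr_type == "compound":
            rec = {
                "type": "compound",
                "members": [
                    {"type": x.ssr_type, "motif": x.motif.split(")")[0][1:], "reps": x.repeats}
                    for x in m.members
                ],
            }
        else:
            rec = {"type": m.ssr_type, "motif": m.motif.split(")")[0][1:], "reps": m.repeats}
        got.setdefault(m.transcript_id, []).append(rec)
    assert got == sim.truth["ssr"]
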