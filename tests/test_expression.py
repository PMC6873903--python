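import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isoseqtk.expression import (
    CountMatrix,
    DETResult,
    bh_adjust,
    call_dets,
    ddct,
    differential_expression,
    fpkm,
    fpkm_matrix,
    group_gene_patterns,
    log2fc,
    permutation_log_test,
)


class TestFpkm:
    def test_closed_form(self):
        assert fpkm(100, 1000, 1_000_000) == pytest.approx(100.0)

    def test_zero_count_is_zero(self):
        assert fpkm(0, 1234, 5_000_000) == 0.0

    def test_scaling_counts_and_library_leaves_fpkm_unchanged(self):
        base = fpkm(37, 1500, 2_000_000)
        for k in (2, 10, 1000):
            assert fpkm(37 * k, 1500, 2_000_000 * k) == pytest.approx(base)

    def test_degenerate_inputs_are_errors(self):
        with pytest.raises(ValueError):
            fpkm(1, 0, 1000)
        with pytest.raises(ValueError):
            fpkm(1, 1000, 0)


class TestLog2fc:
    def test_finite_contrast(self):
        assert log2fc(2, 8) == pytest.approx(2.0)

    def test_silent_seawater_is_minus_inf(self):
        assert log2fc(4, 0) == -math.inf

    def test_silent_freshwater_is_plus_inf(self):
        assert log2fc(0, 4) == math.inf

    def test_both_silent_is_na(self):
        assert log2fc(0, 0) is None


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_never_decreases_p(self):
        ps = [0.001, 0.5, 0.04, 0.9, 0.2]
        assert all(q >= p for p, q in zip(ps, bh_adjust(ps)))

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_brute_force_step_up_adjustment(self, ps):
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        brute = [0.0] * m
        running_min = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running_min = min(running_min, ps[i] * m / rank)
            brute[i] = running_min
        assert bh_adjust(ps) == pytest.approx(brute)


class TestCallDets:
    def make(self, fdr, lfc):
        r = DETResult("t", "g", 1, 1, lfc, 0.01, fdr)
        return call_dets([r])[0]

    def test_both_thresholds_met_flags_up(self):
        r = self.make(0.04, 1.2)
        assert r.is_det and r.direction == "up"

    def test_fdr_above_threshold_not_det(self):
        assert not self.make(0.06, 3.0).is_det

    def test_published_style_row_flags_down(self):
        r = self.make(1.42e-15, -6.264)
        assert r.is_det and r.direction == "down"

    def test_infinite_fold_change_counts(self):
        assert self.make(0.001, math.inf).direction == "up"
        assert self.make(0.001, -math.inf).direction == "down"

    def test_na_fold_change_never_flagged(self):
        assert not self.make(0.001, None).is_det

    def test_small_fold_change_not_det(self):
        assert not self.make(0.001, 0.7).is_det


class TestGenePatterns:
    def res(self, tid, gene, lfc):
        r = DETResult(tid, gene, 1, 1, lfc, 1e-6, 1e-5)
        return r

    def test_all_down_transcripts_are_similar(self):
        rs = call_dets(
            [self.res(f"t{i}", "cdo1", v) for i, v in enumerate([-6.264, -5.180, -5.036])]
        )
        pats = group_gene_patterns(rs)
        assert len(pats) == 1 and pats[0].pattern == "similar"

    def test_mixed_signs_are_opposite(self):
        rs = call_dets([self.res("t1", "decr1", -2.725), self.res("t2", "decr1", 1.047)])
        assert group_gene_patterns(rs)[0].pattern == "opposite"

    def test_single_det_genes_are_excluded(self):
        rs = call_dets([self.res("t1", "g1", 2.0)])
        assert group_gene_patterns(rs) == []


class TestDdct:
    def test_zero_delta_delta_is_one(self):
        assert ddct(20, 15, 20, 15) == 1.0

    def test_one_cycle_halves_expression(self):
        assert ddct(20, 15, 21, 15) == 0.5

    def test_hand_computed_example(self):
        # ddCT = (18-15) - (20-15) = -2 -> 4-fold
        assert ddct(20, 15, 18, 15) == 4.0


class TestDifferentialExpression:
    def small_matrix(self):
        # ballast keeps library sizes equal so FPKM preserves the contrasts
        counts = pd.DataFrame(
            {
                "FW_1": [100, 50, 0, 0, 850],
                "FW_2": [110, 55, 0, 0, 835],
                "SW_1": [400, 52, 80, 0, 468],
                "SW_2": [420, 49, 90, 0, 441],
            },
            index=["up", "flat", "on", "silent", "ballast"],
        )
        return CountMatrix(
            counts=counts,
            condition={"FW_1": "FW", "FW_2": "FW", "SW_1": "SW", "SW_2": "SW"},
            gene_of={t: t for t in counts.index},
            lengths={t: 1000 for t in counts.index},
        )

    def test_directions_and_na_handling(self):
        results = {r.transcript_id: r for r in differential_expression(self.small_matrix())}
        assert results["up"].log2fc > 1
        assert abs(results["flat"].log2fc) < 0.5
        assert results["on"].log2fc == math.inf
        assert results["silent"].log2fc is None and not results["silent"].is_det

    def test_up_down_counts_partition_dets(self, sim):
        from isoseqtk.expression import det_counts

        results = differential_expression(sim.counts)
        counts = det_counts(results)
        assert counts["up"] + counts["down"] == sum(1 for r in results if r.is_det)

    def test_permutation_test_granularity(self):
        fw = np.array([10.0, 11.0, 9.0])
        sw = np.array([100.0, 95.0, 105.0])
        p = permutation_log_test(fw, sw)
        assert p == pytest.approx(2 / 20)  # exact floor at n = 3 + 3


def test_fpkm_matrix_columns_sum_consistency(sim):
    f = fpkm_matrix(sim.counts)
    tid = sim.counts.counts.index[0]
    s = sim.counts.counts.columns[0]
    manual = fpkm(
        sim.counts.counts.loc[tid, s],
        sim.counts.lengths[tid],
        sim.counts.counts[s].sum(),
    )
    assert f.loc[tid, s] == pytest.approx(manual)
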