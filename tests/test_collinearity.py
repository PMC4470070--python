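"""Anchors, chaining, the C statistic, insert calls and the overlap matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import dense_match_coverage, exhaustive_best_chain

from haplotile.collinearity import (
    Anchor,
    chain_anchors,
    classify_band,
    collinearity_C,
    compare,
    detect_inserts,
    find_anchors,
    overlap_matrix,
    recovery_percent,
    trim_segments,
)
from haplotile.errors import InputError
from haplotile.sequtil import random_sequence, revcomp


class TestAnchors:
    def test_identical_sequences_one_full_anchor(self, rng):
        s = random_sequence(rng, 3_000)
        anchors = find_anchors(s, s, w=20)
        plus = [a for a in anchors if a.strand == "+"]
        assert any(a.x == 0 and a.y == 0 and a.length == 3_000 for a in plus)

    def test_reverse_complement_detected_on_minus_strand(self, rng):
        s = random_sequence(rng, 2_000)
        anchors = find_anchors(s, revcomp(s), w=20)
        minus = [a for a in anchors if a.strand == "-"]
        assert any(a.length == 2_000 for a in minus)

    def test_independent_sequences_have_no_anchors(self, rng):
        # expected anchor count 2 * (10^4)^2 * 4^-20 << 1
        a = random_sequence(rng, 10_000)
        b = random_sequence(rng, 10_000)
        assert find_anchors(a, b, w=20) == []

    def test_empty_or_short_input_gives_empty_list(self, rng):
        s = random_sequence(rng, 100)
        assert find_anchors(s[:0], s, w=20) == []
        assert find_anchors(s[:10], s, w=20) == []

    def test_word_length_bounds(self, rng):
        s = random_sequence(rng, 100)
        with pytest.raises(InputError):
            find_anchors(s, s, w=7)
        with pytest.raises(InputError):
            find_anchors(s, s, w=33)

    def test_anchors_are_maximal_exact_matches(self, rng):
        a = random_sequence(rng, 4_000)
        b = a.copy()
        b[1_000] = (b[1_000] + 1) % 4  # single mismatch splits the diagonal
        anchors = sorted((x for x in find_anchors(a, b, w=20) if x.strand == "+"),
                         key=lambda x: x.x)
        assert [x.length for x in anchors] == [1_000, 2_999]
        for x in anchors:
            assert np.array_equal(a[x.x:x.x + x.length], b[x.y:x.y + x.length])


class TestChaining:
    def test_single_anchor_single_segment(self):
        segs = chain_anchors([Anchor(10, 10, 50, "+")])
        assert len(segs) == 1
        s = segs[0]
        assert (s.a_start, s.a_end, s.b_start, s.b_end) == (10, 60, 10, 60)

    def test_small_gap_merges_into_one_segment(self):
        anchors = [Anchor(0, 0, 100, "+"), Anchor(5_100, 5_100, 100, "+")]
        segs = chain_anchors(anchors, max_gap=10_000, max_diag_drift=5_000)
        assert len(segs) == 1

    def test_gap_beyond_limit_splits(self):
        anchors = [Anchor(0, 0, 100, "+"), Anchor(20_000, 20_000, 100, "+")]
        segs = chain_anchors(anchors, max_gap=10_000, max_diag_drift=5_000)
        assert len(segs) == 2

    def test_off_diagonal_duplication_gives_separate_trimmed_segments(self, rng):
        # B carries two tandem copies of a block of A
        block = random_sequence(rng, 4_000)
        flank = random_sequence(rng, 3_000)
        a = np.concatenate([flank, block, flank[::-1]])
        b = np.concatenate([flank, block, block, flank[::-1]])
        # drift tolerance below the duplication offset so the copies
        # resolve into separate diagonal bands
        segs = trim_segments(chain_anchors(find_anchors(a, b, w=20),
                                           max_diag_drift=2_000, len_b=len(b)))
        assert len(segs) >= 2
        for s1 in segs:
            for s2 in segs:
                if s1 is s2:
                    continue
                assert s1.a_end <= s2.a_start or s2.a_end <= s1.a_start
                assert s1.b_end <= s2.b_start or s2.b_end <= s1.b_start

    def test_matches_exhaustive_chain_oracle_on_small_inputs(self, rng):
        for trial in range(5):
            a = random_sequence(rng, 3_000)
            b = a.copy()
            idx = rng.choice(len(b), 12, replace=False)
            b[idx] = (b[idx] + 1) % 4
            anchors = [x for x in find_anchors(a, b, w=20) if x.strand == "+"]
            assert len(anchors) <= 20
            best = exhaustive_best_chain(anchors, 10_000, 5_000)
            segs = trim_segments(chain_anchors(anchors, 10_000, 5_000, len_b=len(b)))
            covered = sum(s.len_a for s in segs)
            assert covered >= 0.95 * best


class TestCStatistic:
    def test_identical_sequences_give_full_collinearity(self, rng):
        s = random_sequence(rng, 5_000)
        res = compare(s, s)
        assert res.C == 1.0
        assert res.O == res.L1 == res.L2
        assert res.band == "green"

    def test_threshold_arithmetic(self):
        from haplotile.collinearity import CollinearSegment

        segs = [CollinearSegment(0, 75_000, 0, 75_000, "+", 1, 75_000)]
        res = collinearity_C(segs, 100_000, 100_000)
        assert res.C == pytest.approx(0.75)
        assert res.band == "green"

    def test_no_segments_is_red_zero(self):
        res = collinearity_C([], 10_000, 10_000)
        assert res.C == 0.0 and res.band == "red"

    def test_zero_length_inputs_rejected(self):
        with pytest.raises(InputError):
            collinearity_C([], 0, 100)

    def test_symmetry_exact(self, rng):
        a = random_sequence(rng, 6_000)
        b = a.copy()
        idx = rng.choice(len(b), 120, replace=False)
        b[idx] = (b[idx] + rng.integers(1, 4, 120).astype(np.uint8)) % 4
        assert compare(a, b).C == compare(b, a).C

    def test_additivity_of_independent_blocks(self, rng):
        blk1, blk2 = random_sequence(rng, 4_000), random_sequence(rng, 4_000)
        gap_a, gap_b = random_sequence(rng, 2_000), random_sequence(rng, 2_000)
        a = np.concatenate([blk1, gap_a, blk2])
        b = np.concatenate([blk1, gap_b, blk2])
        o_joint = compare(a, b, max_gap=1_000).O
        o1 = compare(blk1, blk1).O
        o2 = compare(blk2, blk2).O
        assert abs(o_joint - (o1 + o2)) <= 2 * 20

    def test_monotone_degradation_with_divergence(self, rng):
        base = random_sequence(rng, 20_000)
        b = base.copy()
        cs = []
        for extra in (0.0, 0.01, 0.02, 0.03, 0.04):
            # nested mutation sets: each step adds substitutions on top of
            # the previous ones, so divergence strictly accumulates
            mask = rng.random(len(b)) < extra
            b[mask] = (b[mask] + rng.integers(1, 4, int(mask.sum())).astype(np.uint8)) % 4
            cs.append(compare(base, b).C)
        assert all(c1 >= c2 - 1e-9 for c1, c2 in zip(cs, cs[1:]))

    def test_oracle_equivalence_on_block_structured_pairs(self, rng):
        # On pairs made of identical blocks embedded in unrelated sequence,
        # O agrees with a dense diagonal-scan coverage oracle within 5%.
        for trial in range(3):
            x = random_sequence(rng, 2_000)
            y = random_sequence(rng, 1_500)
            a = np.concatenate([x, random_sequence(rng, 800), y])
            b = np.concatenate([random_sequence(rng, 500), x,
                                random_sequence(rng, 700), y])
            # gap parameters scaled to the kb-sized problem so unrelated
            # spacers are not bridged into one segment
            res = compare(a, b, max_gap=300, max_diag_drift=300)
            cov_a, cov_b = dense_match_coverage(a, b, 20)
            oracle_o = (cov_a + cov_b) / 2
            assert oracle_o == pytest.approx(3_500, abs=100)
            assert res.O == pytest.approx(oracle_o, rel=0.05)


class TestRecoveryAndBands:
    @pytest.mark.parametrize("o,l,expected", [
        (2_550, 10_004, 25.5),
        (2_104, 10_004, 21.0),
        (7, 7, 100.0),
    ])
    def test_recovery_percent(self, o, l, expected):
        assert round(recovery_percent(o, l), 1) == expected

    def test_recovery_domain_errors(self):
        with pytest.raises(InputError):
            recovery_percent(1, 0)
        with pytest.raises(InputError):
            recovery_percent(5, 4)

    @pytest.mark.parametrize("c,band", [
        (0.80, "green"), (0.75, "green"), (0.60, "yellow"),
        (0.30, "orange"), (0.10, "red"), (0.0, "red"), (1.0, "green"),
    ])
    def test_band_classification(self, c, band):
        assert classify_band(c) == band

    def test_band_domain_error(self):
        with pytest.raises(InputError):
            classify_band(1.5)

    @given(st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_band_total_and_ordered(self, c):
        assert classify_band(c) in ("green", "yellow", "orange", "red")


class TestInserts:
    def _pair_with_insert(self, rng, ins_len):
        left = random_sequence(rng, 30_000)
        right = random_sequence(rng, 30_000)
        ins = random_sequence(rng, ins_len)
        a = np.concatenate([left, ins, right])
        b = np.concatenate([left, right])
        return a, b

    def test_planted_insert_called_with_accurate_size(self, rng):
        a, b = self._pair_with_insert(rng, 30_000)
        res = compare(a, b)
        assert len(res.inserts) == 1
        call = res.inserts[0]
        assert call.carrier == "A"
        assert abs(call.length - 30_000) <= 20
        assert abs(call.start - 30_000) <= 20

    def test_carrier_side_detection(self, rng):
        a, b = self._pair_with_insert(rng, 25_000)
        res = compare(b, a)  # insert now on the B side
        assert len(res.inserts) == 1 and res.inserts[0].carrier == "B"

    def test_insert_below_threshold_not_called(self, rng):
        a, b = self._pair_with_insert(rng, 10_000)
        res = compare(a, b, min_insert=20_000)
        assert res.inserts == []

    def test_identical_sequences_no_calls(self, rng):
        s = random_sequence(rng, 50_000)
        assert compare(s, s).inserts == []


class TestOverlapMatrix:
    def test_self_recovery_is_100(self, rng):
        s1, s2 = random_sequence(rng, 8_000), random_sequence(rng, 8_000)
        m = overlap_matrix({"x": [s1], "y": [s1.copy(), s2]})
        assert m.recovery[0, 0] == 100.0
        # x is fully contained in y
        assert m.recovery[0, 1] == pytest.approx(100.0, abs=1.0)

    def test_disjoint_sets_recover_nothing(self, rng):
        m = overlap_matrix({
            "x": [random_sequence(rng, 10_000)],
            "y": [random_sequence(rng, 10_000)],
        })
        assert m.recovery[0, 1] <= 1.0 and m.recovery[1, 0] <= 1.0
        assert m.O_kb[0, 1] == 0.0

    def test_planted_shared_fraction_recovered(self, rng):
        # one quarter of set x's sequence is present (rearranged) in y
        shared = random_sequence(rng, 5_000)
        x = np.concatenate([random_sequence(rng, 7_500), shared, random_sequence(rng, 7_500)])
        y = np.concatenate([shared, random_sequence(rng, 15_000)])
        m = overlap_matrix({"x": [x], "y": [y]})
        assert m.recovery[0, 1] == pytest.approx(25.0, abs=3.0)

    def test_single_set_rejected(self, rng):
        with pytest.raises(InputError):
            overlap_matrix({"x": [random_sequence(rng, 1_000)]})

    def test_empty_set_rejected(self, rng):
        with pytest.raises(InputError):
            overlap_matrix({"x": [random_sequence(rng, 1_000)], "y": []})

    def test_table_layout(self, rng):
        m = overlap_matrix({
            "x": [random_sequence(rng, 5_000)],
            "y": [random_sequence(rng, 5_000)],
        })
        df = m.to_frame()
        assert list(df.columns[:2]) == ["n_sequences", "total_kb"]
        assert df.loc["x", "x"] == "--"
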