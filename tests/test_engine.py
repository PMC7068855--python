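"""Scan engine: encoding, matrix layout, score blocks, oracle equivalence."""

import itertools

import numpy as np
import pytest

from pwmgemm import (
    PWM,
    ScanConfig,
    build_pattern_matrix,
    build_sequence_matrix,
    encode_sequence,
    extract_occurrences,
    naive_scan,
    reverse_complement,
    scan_stream,
    score_block,
    score_window,
    thresholds_for_motifs,
)
from pwmgemm.engine import ScoreBlock, SequenceChunk, dna_to_codes
from pwmgemm.motifs import reverse_complement_dna

from helpers import occ_keys, random_pwms, random_records


def make_chunk(dna, h, w, m, record_ids=("r0",), rec_index=None, rec_pos=None, **kw):
    codes = dna_to_codes(dna)
    n = len(codes)
    if rec_index is None:
        rec_index = np.zeros(n, dtype=np.int64)
    if rec_pos is None:
        rec_pos = np.arange(n, dtype=np.int64)
    return SequenceChunk(
        chunk_index=0, codes=codes, rec_index=np.asarray(rec_index),
        rec_pos=np.asarray(rec_pos), h=h, w=w, m=m, record_ids=list(record_ids), **kw
    )


class TestEncodeSequence:
    def test_acgt_onehot(self):
        expected = [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1]
        np.testing.assert_array_equal(encode_sequence("ACGT"), expected)

    def test_non_acgt_all_zeros(self):
        np.testing.assert_array_equal(encode_sequence("N"), [0, 0, 0, 0])

    def test_empty(self):
        assert encode_sequence("").shape == (0,)

    def test_lowercase_uppercased(self):
        np.testing.assert_array_equal(encode_sequence("acgt"), encode_sequence("ACGT"))


class TestPatternMatrix:
    def test_trailing_zeros_layout(self):
        pwms = [
            PWM("long", np.arange(8, dtype=float).reshape(4, 2)),
            PWM("short", np.arange(4, dtype=float).reshape(4, 1) + 10),
        ]
        P = build_pattern_matrix(pwms, include_rc=False)
        assert P.values.shape == (8, 2)
        np.testing.assert_array_equal(P.values[4:, 1], np.zeros(4))
        # unrolled column: P(i,j) = W(i mod 4, i // 4)
        for i in range(8):
            assert P.values[i, 0] == pwms[0].weights[i % 4, i // 4]

    def test_reverse_complement_columns(self):
        pwms = [
            PWM("a", np.arange(8, dtype=float).reshape(4, 2)),
            PWM("b", np.arange(4, dtype=float).reshape(4, 1)),
        ]
        P = build_pattern_matrix(pwms, include_rc=True)
        assert P.values.shape == (8, 4)
        assert [c.strand for c in P.columns] == ["+", "+", "-", "-"]
        rc = reverse_complement(pwms[0])
        np.testing.assert_array_equal(P.values[:8, 2], rc.weights.T.ravel())

    def test_all_zero_pwm_column(self):
        P = build_pattern_matrix([PWM("z", np.zeros((4, 2)))], include_rc=False)
        np.testing.assert_array_equal(P.values, np.zeros((8, 1)))

    def test_empty_motif_list_rejected(self):
        with pytest.raises(ValueError, match="at least one motif"):
            build_pattern_matrix([], include_rc=True)


class TestSequenceMatrix:
    def test_layout_and_row_overlap(self):
        S = build_sequence_matrix(encode_sequence("ACGTACG"), h=2, w=3, m=2)
        assert S.shape == (2, 16)
        np.testing.assert_array_equal(S[0], encode_sequence("ACGT"))
        np.testing.assert_array_equal(S[1], encode_sequence("TACG"))
        np.testing.assert_array_equal(S[0, 12:16], S[1, 0:4])

    def test_degenerate_1x1(self):
        S = build_sequence_matrix(encode_sequence("C"), h=1, w=1, m=1)
        np.testing.assert_array_equal(S, [[0, 1, 0, 0]])

    def test_zero_encoding_inside_layout(self):
        S = build_sequence_matrix(encode_sequence("ANA"), h=1, w=2, m=2)
        np.testing.assert_array_equal(
            S, [[1, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0]]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="h\\*w\\+m-1"):
            build_sequence_matrix(encode_sequence("ACGT"), h=2, w=3, m=2)


class TestScoreBlock:
    def test_hand_dot_product(self, toy_pwm_m2):
        P = build_pattern_matrix([toy_pwm_m2], include_rc=False)
        S = build_sequence_matrix(encode_sequence("AC"), h=1, w=1, m=2)
        block = score_block(S, P, 0)
        assert block.values[0, 0] == 0.0  # 1 + (-1)

    def test_all_zero_pattern_column(self):
        P = build_pattern_matrix([PWM("z", np.zeros((4, 2)))], include_rc=False)
        S = build_sequence_matrix(encode_sequence("ACGTA"), h=2, w=2, m=2)
        np.testing.assert_array_equal(score_block(S, P, 1).values, np.zeros((2, 1)))

    def test_n_reduces_score_by_a_row_entry(self, toy_pwm_m2):
        P = build_pattern_matrix([toy_pwm_m2], include_rc=False)
        S_aa = build_sequence_matrix(encode_sequence("AA"), h=1, w=1, m=2)
        S_an = build_sequence_matrix(encode_sequence("AN"), h=1, w=1, m=2)
        delta = score_block(S_aa, P, 0).values[0, 0] - score_block(S_an, P, 0).values[0, 0]
        assert delta == toy_pwm_m2.weights[0, 1]  # the A-row entry at position 1

    def test_matches_score_window_everywhere(self):
        pwms = random_pwms(4, (2, 5), seed=21)
        P = build_pattern_matrix(pwms, include_rc=True)
        dna = "ACGTTTGACNACGTACGGTA"[: 3 * 4 + P.m - 1]
        h, w = 3, 4
        S = build_sequence_matrix(encode_sequence(dna), h, w, P.m)
        for o in range(w):
            block = score_block(S, P, o)
            for i in range(h):
                pos = i * w + o
                for j, col in enumerate(P.columns):
                    window = dna[pos:pos + col.length]
                    pwm = pwms[col.index % len(pwms)]
                    if col.strand == "-":
                        pwm = reverse_complement(pwm)
                    assert block.values[i, j] == pytest.approx(
                        score_window(pwm, window), abs=1e-4
                    )

    def test_offset_out_of_range(self, toy_pwm_m2):
        P = build_pattern_matrix([toy_pwm_m2], include_rc=False)
        S = build_sequence_matrix(encode_sequence("ACGTA"), h=2, w=2, m=2)
        with pytest.raises(ValueError, match="offset"):
            score_block(S, P, 2)


class TestExtractOccurrences:
    def test_boundary_equality_admitted(self, toy_pwm_m2):
        P = build_pattern_matrix([toy_pwm_m2], include_rc=False)
        chunk = make_chunk("AC", h=1, w=1, m=2)
        block = ScoreBlock(values=np.array([[0.0]]), offset=0)
        occs = extract_occurrences(block, P, {"toy2": 0.0}, chunk)
        assert len(occs) == 1 and occs[0].start == 0

    def test_record_straddling_window_suppressed(self, toy_pwm_m2):
        P = build_pattern_matrix([toy_pwm_m2], include_rc=False)
        # two records "A" + sentinel-free junction: positions 0 and 1 belong
        # to different records, so the m=2 window at 0 must be dropped
        chunk = make_chunk("AA", h=1, w=1, m=2, record_ids=["x", "y"],
                           rec_index=[0, 1], rec_pos=[0, 0])
        block = ScoreBlock(values=np.array([[99.0]]), offset=0)
        assert extract_occurrences(block, P, {"toy2": -100.0}, chunk) == []

    def test_padding_suppressed(self, toy_pwm_m2):
        P = build_pattern_matrix([toy_pwm_m2], include_rc=False)
        chunk = make_chunk("AN", h=1, w=1, m=2, rec_index=[0, -1], rec_pos=[0, -1])
        block = ScoreBlock(values=np.array([[99.0]]), offset=0)
        assert extract_occurrences(block, P, {"toy2": -100.0}, chunk) == []

    def test_missing_threshold_rejected(self, toy_pwm_m2):
        P = build_pattern_matrix([toy_pwm_m2], include_rc=False)
        chunk = make_chunk("AC", h=1, w=1, m=2)
        block = ScoreBlock(values=np.array([[0.0]]), offset=0)
        with pytest.raises(KeyError, match="toy2"):
            extract_occurrences(block, P, {"other": 0.0}, chunk)


class TestScanStream:
    def test_two_records_never_bridge(self):
        aa = PWM("aa", np.array([[1.0, 1.0], [-9, -9], [-9, -9], [-9, -9]]))
        res = scan_stream([("r1", "AAA"), ("r2", "AAA")], [aa],
                          thresholds={"aa": 2.0}, include_rc=False, h=1, w=1)
        assert occ_keys(res.occurrences) == [
            ("r1", 0, "aa", "+"), ("r1", 1, "aa", "+"),
            ("r2", 0, "aa", "+"), ("r2", 1, "aa", "+"),
        ]
        assert res.n == 6 and res.n_occ == 4

    def test_empty_record_list(self, toy_pwm_m2):
        with pytest.warns(UserWarning):  # every motif is longer than no record
            res = scan_stream([], [toy_pwm_m2], thresholds={"toy2": 0.0})
        assert res.occurrences == [] and res.n == 0

    def test_zero_length_record_scanned_without_error(self, toy_pwm_m2):
        res = scan_stream([("r0", ""), ("r1", "ACAC")], [toy_pwm_m2],
                          thresholds={"toy2": -10.0}, include_rc=False, h=2, w=2)
        assert all(o.record == "r1" for o in res.occurrences)

    @pytest.mark.parametrize("geometry", [(1, 1), (7, 3), (1000, 250)])
    def test_chunk_geometry_invariance(self, geometry):
        pwms = random_pwms(6, (3, 9), seed=31)
        records = random_records(4, [137, 81, 260], seed=32)
        baseline = scan_stream(records, pwms, pvalue=0.05, h=5, w=4)
        h, w = geometry
        other = scan_stream(records, pwms, pvalue=0.05, h=h, w=w)
        assert occ_keys(other.occurrences) == occ_keys(baseline.occurrences)
        np.testing.assert_allclose(
            [o.score for o in other.occurrences],
            [o.score for o in baseline.occurrences], atol=1e-9,
        )

    def test_worker_count_invariance(self):
        pwms = random_pwms(5, (4, 8), seed=41)
        records = random_records(3, [400, 350], seed=42)
        one = scan_stream(records, pwms, pvalue=0.02, h=11, w=7, workers=1)
        four = scan_stream(records, pwms, pvalue=0.02, h=11, w=7, workers=4)
        assert one.occurrences == four.occurrences

    def test_matches_naive_scan(self):
        pwms = random_pwms(10, (5, 12), seed=51)
        records = random_records(20, [151, 88, 212], seed=52)
        thresholds = thresholds_for_motifs(pwms, p=1e-2)
        res = scan_stream(records, pwms, thresholds=thresholds, h=13, w=9)
        ref = naive_scan(records, pwms, thresholds)
        assert occ_keys(res.occurrences) == occ_keys(ref)
        np.testing.assert_allclose(
            [o.score for o in res.occurrences], [o.score for o in ref], atol=1e-4
        )

    def test_monotone_in_pvalue(self):
        pwms = random_pwms(5, (5, 9), seed=61)
        records = random_records(3, [500], seed=62)
        loose = scan_stream(records, pwms, pvalue=1e-2)
        tight = scan_stream(records, pwms, pvalue=1e-3)
        assert set(occ_keys(tight.occurrences)) <= set(occ_keys(loose.occurrences))

    def test_exclude_policy_matches_naive(self):
        rng = np.random.default_rng(63)
        seq = "".join(rng.choice(list("ACGTN"), size=300, p=[0.22] * 4 + [0.12]))
        pwms = random_pwms(4, (3, 6), seed=64)
        thresholds = thresholds_for_motifs(pwms, p=0.1)
        res = scan_stream([("r", seq)], pwms, thresholds=thresholds,
                          non_acgt="exclude", h=9, w=5)
        ref = naive_scan([("r", seq)], pwms, thresholds, non_acgt="exclude")
        assert occ_keys(res.occurrences) == occ_keys(ref)
        # and the policies genuinely differ on this N-rich input
        res_zero = scan_stream([("r", seq)], pwms, thresholds=thresholds, h=9, w=5)
        assert len(res_zero.occurrences) > len(res.occurrences)

    def test_motif_longer_than_every_record_warns(self, toy_pwm_m2):
        long_pwm = PWM("long", np.zeros((4, 10)))
        with pytest.warns(UserWarning, match="longer than every record"):
            res = scan_stream([("r", "ACGTA")], [toy_pwm_m2, long_pwm],
                              thresholds={"toy2": 99.0, "long": -99.0})
        assert res.occurrences == []

    def test_config_validation(self, toy_pwm_m2):
        with pytest.raises(ValueError, match="exactly one"):
            ScanConfig(pvalue=0.1, thresholds={"a": 1.0})
        with pytest.raises(ValueError, match="exactly one"):
            ScanConfig()
        with pytest.raises(ValueError, match="h and w"):
            ScanConfig(pvalue=0.1, h=0)


class TestStrandSymmetry:
    def test_minus_hits_map_to_plus_hits_of_revcomp(self):
        pwms = random_pwms(6, (4, 9), seed=71)
        records = random_records(2, [300, 211], seed=72)
        thresholds = thresholds_for_motifs(pwms, p=5e-3)
        fwd = scan_stream(records, pwms, thresholds=thresholds)
        flipped = [(rid, reverse_complement_dna(seq)) for rid, seq in records]
        rev = scan_stream(flipped, pwms, thresholds=thresholds)
        lengths = {rid: len(seq) for rid, seq in records}

        def mirror(occs, strand):
            return sorted(
                (o.record, lengths[o.record] - o.end, o.motif)
                for o in occs if o.strand == strand
            )

        assert mirror(fwd.occurrences, "-") == sorted(
            (o.record, o.start, o.motif)
            for o in rev.occurrences if o.strand == "+"
        )


class TestNaiveScanSelfCheck:
    def test_naive_matches_scalar_score_window(self, toy_pwm_m1):
        """The oracle itself agrees with the scalar primitive on a hand case."""
        hits = naive_scan([("r", "ACAC")], [toy_pwm_m1], {"toy1": 1.0}, include_rc=False)
        assert occ_keys(hits) == [("r", 0, "toy1", "+"), ("r", 2, "toy1", "+")]
        pwms = random_pwms(3, (2, 4), seed=81)
        records = random_records(2, [40], seed=82)
        thresholds = {p.name: -1.0 for p in pwms}
        hits = naive_scan(records, pwms, thresholds)
        for occ in hits:
            seq = dict(records)[occ.record]
            pwm = next(p for p in pwms if p.name == occ.motif)
            if occ.strand == "-":
                pwm = reverse_complement(pwm)
            window = seq[occ.start:occ.start + occ.length]
            assert occ.score == pytest.approx(score_window(pwm, window), abs=1e-12)

    def test_threshold_above_max_empty(self, toy_pwm_m1):
        assert naive_scan([("r", "AAAA")], [toy_pwm_m1], {"toy1": 2.0}) == []
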