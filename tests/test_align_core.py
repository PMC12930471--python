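"""Scalar local / semi-global alignment, traceback, and batch dispatch."""

import numpy as np
import pytest

from conftest import ALL_END_FLAGS, GOLDEN_SCORE, GOLDEN_TARGET_SPAN

from seqsift.align_core import (
    EndFlags,
    batch_align_scalar,
    local_align_scalar,
    semiglobal_align_scalar,
    traceback_span,
)
from seqsift.scoring import encode_sequence, optimal_score


def enc(scheme, s):
    return encode_sequence(scheme, s)


class TestLocalScalar:
    def test_perfect_self_match(self, actgn):
        r = local_align_scalar(actgn, enc(actgn, b"ACGT"), enc(actgn, b"ACGT"))
        assert (r.score, r.query_end, r.target_end) == (8, 3, 3)

    def test_all_mismatch_empty_alignment(self, actgn):
        r = local_align_scalar(actgn, enc(actgn, b"AAAA"), enc(actgn, b"TTTT"))
        assert (r.score, r.query_end, r.target_end) == (0, -1, -1)

    def test_golden_pair(self, golden, py_local_oracle):
        scheme, q, t = golden
        r = local_align_scalar(scheme, q, t)
        assert r.score == GOLDEN_SCORE
        assert r.score == py_local_oracle(scheme, q, t)

    def test_empty_sequence_error(self, actgn):
        with pytest.raises(ValueError):
            local_align_scalar(actgn, enc(actgn, b""), enc(actgn, b"ACGT"))

    def test_score_symmetry(self, all_schemes, make_random_pair):
        rng = np.random.default_rng(3)
        for name in ("actgn", "blosum62", "ascii"):
            for _ in range(20):
                scheme, q, t = make_random_pair(rng, name, max_len=60)
                assert (local_align_scalar(scheme, q, t).score
                        == local_align_scalar(scheme, t, q).score)

    def test_concatenation_monotonicity(self, actgn, make_random_pair):
        """local(q, t1 + t2) >= max(local(q, t1), local(q, t2))."""
        rng = np.random.default_rng(4)
        for _ in range(30):
            _, q, t1 = make_random_pair(rng, "actgn", max_len=50)
            _, _, t2 = make_random_pair(rng, "actgn", max_len=50)
            joint = local_align_scalar(actgn, q, np.concatenate([t1, t2])).score
            assert joint >= max(local_align_scalar(actgn, q, t1).score,
                                local_align_scalar(actgn, q, t2).score)


class TestSemiglobalScalar:
    def test_global_with_single_deletion(self, actgn):
        # ACGT vs AGT: 3 matches minus one length-1 gap (cost 3)
        r = semiglobal_align_scalar(actgn, enc(actgn, b"ACGT"),
                                    enc(actgn, b"AGT"), EndFlags.global_())
        assert r.score == 3

    def test_golden_default_flags(self, golden):
        scheme, q, t = golden
        r = semiglobal_align_scalar(scheme, q, t, EndFlags())
        assert r.score == GOLDEN_SCORE
        assert r.target_end == GOLDEN_TARGET_SPAN[1] - 1

    def test_self_alignment_any_flags(self, actgn, golden):
        scheme, q, _ = golden
        opt = optimal_score(scheme, q)
        for ends in ALL_END_FLAGS:
            assert semiglobal_align_scalar(scheme, q, q, ends).score == opt

    def test_matches_python_oracle_all_flags(self, make_random_pair,
                                             py_semiglobal_oracle):
        rng = np.random.default_rng(5)
        for trial in range(48):
            name = ("actgn", "blosum62", "ascii")[trial % 3]
            scheme, q, t = make_random_pair(rng, name, max_len=40)
            ends = ALL_END_FLAGS[trial % 16]
            assert (semiglobal_align_scalar(scheme, q, t, ends).score
                    == py_semiglobal_oracle(scheme, q, t, ends))

    def test_empty_sequence_error(self, actgn):
        with pytest.raises(ValueError):
            semiglobal_align_scalar(actgn, enc(actgn, b"A"), enc(actgn, b""))


class TestTraceback:
    def test_golden_span(self, golden):
        scheme, q, t = golden
        r = semiglobal_align_scalar(scheme, q, t, EndFlags())
        span = traceback_span(scheme, q, t, "semiglobal", EndFlags(), r)
        assert (span.target_start, span.target_end) == GOLDEN_TARGET_SPAN
        assert (span.query_start, span.query_end) == (0, len(q))
        assert span.score == r.score

    def test_self_alignment_full_span(self, actgn):
        q = enc(actgn, b"ACGTACGT")
        r = local_align_scalar(actgn, q, q)
        span = traceback_span(actgn, q, q, "local", EndFlags(), r)
        assert (span.query_start, span.query_end) == (0, 8)
        assert (span.target_start, span.target_end) == (0, 8)

    def test_local_exact_submatch(self, actgn):
        q = enc(actgn, b"AAAA")
        t = enc(actgn, b"GGAAAAGG")
        r = local_align_scalar(actgn, q, t)
        span = traceback_span(actgn, q, t, "local", EndFlags(), r)
        assert (span.target_start, span.target_end) == (2, 6)

    @pytest.mark.parametrize("mode", ["local", "semiglobal"])
    def test_span_score_matches_result(self, make_random_pair, mode):
        rng = np.random.default_rng(6)
        for trial in range(40):
            name = ("actgn", "blosum62", "ascii")[trial % 3]
            ends = ALL_END_FLAGS[trial % 16]
            scheme, q, t = make_random_pair(rng, name, max_len=60)
            if mode == "local":
                r = local_align_scalar(scheme, q, t)
                if r.query_end < 0:
                    continue
            else:
                r = semiglobal_align_scalar(scheme, q, t, ends)
                if r.query_end < 0 or r.target_end < 0:
                    continue
            span = traceback_span(scheme, q, t, mode, ends, r)
            assert span.score == r.score
            assert 0 <= span.query_start <= span.query_end <= len(q)
            assert 0 <= span.target_start <= span.target_end <= len(t)

    def test_empty_alignment_rejected(self, actgn):
        q, t = enc(actgn, b"AAAA"), enc(actgn, b"TTTT")
        r = local_align_scalar(actgn, q, t)
        with pytest.raises(ValueError):
            traceback_span(actgn, q, t, "local", EndFlags(), r)


class TestBatch:
    def test_matches_individual_alignment(self, actgn, make_random_pair):
        rng = np.random.default_rng(8)
        _, q, _ = make_random_pair(rng, "actgn", max_len=40)
        targets = [make_random_pair(rng, "actgn", max_len=80)[2]
                   for _ in range(17)]
        for cf in (1, 2, 5, 100):
            batch = batch_align_scalar(actgn, q, targets, "semiglobal",
                                       EndFlags(), coarse_factor=cf)
            for res, t in zip(batch, targets):
                solo = semiglobal_align_scalar(actgn, q, t, EndFlags())
                assert (res.score, res.query_end, res.target_end) == \
                    (solo.score, solo.query_end, solo.target_end)

    def test_empty_target_list(self, actgn):
        assert batch_align_scalar(actgn, enc(actgn, b"ACGT"), []) == []

    def test_result_count(self, actgn):
        q = enc(actgn, b"ACGT")
        targets = [enc(actgn, b"ACGT")] * 5
        assert len(batch_align_scalar(actgn, q, targets, coarse_factor=2)) == 5

    def test_bad_coarse_factor(self, actgn):
        with pytest.raises(ValueError):
            batch_align_scalar(actgn, enc(actgn, b"A"), [], coarse_factor=0)

    def test_error_names_offending_index(self, actgn):
        q = enc(actgn, b"ACGT")
        targets = [enc(actgn, b"ACGT"), enc(actgn, b"")]
        with pytest.raises(ValueError, match="target 1"):
            batch_align_scalar(actgn, q, targets)
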