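"""Alignment engine: λ calibration, Smith-Waterman, E-values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from venomest.align import (
    CalibrationError,
    ScoringScheme,
    SearchSpace,
    evalue_of,
    min_score_for_evalue,
    reverse_complement,
    search_both_strands,
    smith_waterman,
    solve_lambda,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


# ---------------------------------------------------------------------------
# independent oracle: plain-python affine-gap local alignment DP
# ---------------------------------------------------------------------------


def oracle_best_score(q, s, match, mismatch, gap_open, gap_extend):
    """Three-state affine local alignment, written independently."""
    m, n = len(q), len(s)
    NEG = -(10 ** 9)
    best = 0
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open + gap_extend,
                          E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open + gap_extend,
                          F[i - 1][j] + gap_extend)
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSolveLambda:
    def test_unit_scheme_has_closed_form_root(self):
        scheme = ScoringScheme(match=1, mismatch=-1, gap_open=-1, gap_extend=-1)
        # 0.25 x + 0.75 / x = 1 with x = e^lambda  ->  x = 3
        assert solve_lambda(scheme) == pytest.approx(math.log(3), rel=1e-9)

    def test_nonnegative_expected_score_is_an_error(self):
        scheme = ScoringScheme(match=1, mismatch=-1, gap_open=-1, gap_extend=-1,
                               background=(0.97, 0.01, 0.01, 0.01))
        assert scheme.expected_score >= 0
        with pytest.raises(CalibrationError):
            solve_lambda(scheme)

    def test_agrees_with_independent_bisection(self):
        scheme = ScoringScheme(match=2, mismatch=-3, gap_open=-5, gap_extend=-2)

        def f(lam):
            # sum over ordered letter pairs under uniform background
            return (4 * 0.0625 * math.exp(lam * 2)
                    + 12 * 0.0625 * math.exp(lam * -3)) - 1.0

        lo, hi = 1e-9, 4.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert solve_lambda(scheme) == pytest.approx((lo + hi) / 2, rel=1e-9)


class TestSmithWaterman:
    def test_exact_substring(self, unit_scheme):
        scheme = ScoringScheme(match=1, mismatch=-1, gap_open=-1, gap_extend=-1,
                               lam=unit_scheme.lam)
        hits = smith_waterman("ACGT", "TACGTA", scheme)
        a = hits[0]
        assert (a.score, a.identity) == (4, 1.0)
        assert (a.q_start, a.q_end, a.s_start, a.s_end) == (0, 4, 1, 5)

    def test_self_alignment_scores_full_length(self, scheme):
        seq = "ACGTACGTCCGGATTA"
        a = smith_waterman(seq, seq, scheme)[0]
        assert a.score == scheme.match * len(seq)
        assert a.identity == 1.0

    def test_empty_sequence_rejected(self, scheme):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT", scheme)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(q=DNA, s=DNA)
    def test_score_matches_exhaustive_oracle(self, q, s, scheme):
        hits = smith_waterman(q, s, scheme, min_score=1)
        got = hits[0].score if hits else 0
        want = oracle_best_score(q, s, scheme.match, scheme.mismatch,
                                 scheme.gap_open, scheme.gap_extend)
        assert got == want

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(q=DNA, s=DNA)
    def test_reversal_symmetry(self, q, s, scheme):
        a = smith_waterman(q, s, scheme, min_score=1)
        b = smith_waterman(s, q, scheme, min_score=1)
        assert (a[0].score if a else 0) == (b[0].score if b else 0)

    def test_multi_hits_never_overlap_on_query(self, scheme, rng):
        from conftest import random_seq
        core = random_seq(rng, 40)
        query = core + random_seq(rng, 30) + core
        hits = smith_waterman(query, core, scheme, min_score=20)
        assert len(hits) == 2
        (a, b) = sorted(hits, key=lambda h: h.q_start)
        assert a.q_end <= b.q_start

    def test_column_counts_sum(self, scheme, rng):
        from conftest import random_seq
        s = random_seq(rng, 200)
        q = s[30:150]
        q = q[:50] + "T" + q[51:]  # one substitution
        a = smith_waterman(q, s, scheme)[0]
        assert a.matches + a.mismatches + a.gap_columns == a.aligned_length


class TestBothStrands:
    def test_reverse_complement_hit(self, scheme, rng):
        from conftest import random_seq
        subject = random_seq(rng, 120)
        query = reverse_complement(subject[20:80])
        hits = search_both_strands(query, subject, scheme, min_score=30)
        assert hits[0].strand == "reverse"
        assert hits[0].identity == 1.0
        # query coordinates are on the forward strand of the query
        assert (hits[0].q_start, hits[0].q_end) == (0, 60)

    def test_unrelated_sequences_no_hit(self, scheme, rng):
        from conftest import random_seq
        q, s = random_seq(rng, 80), random_seq(rng, 80)
        assert search_both_strands(q, s, scheme, min_score=40) == []

    def test_no_duplicate_interval_reports(self, scheme, rng):
        from conftest import random_seq
        s = random_seq(rng, 150)
        q = s[10:110]
        hits = search_both_strands(q, s, scheme, min_score=30)
        keys = [(h.q_start, h.q_end, h.s_start, h.s_end, h.strand) for h in hits]
        assert len(keys) == len(set(keys))


class TestEvalues:
    def test_direct_arithmetic(self):
        scheme = ScoringScheme(match=1, mismatch=-1, gap_open=-1, gap_extend=-1,
                               lam=math.log(3), k_const=0.5)
        space = SearchSpace(100, 1000)
        # K m n e^(-lambda S) = 0.5 * 1e5 * 3^-10
        assert evalue_of(10, space, scheme) == pytest.approx(
            0.5 * 1e5 * 3.0 ** -10, rel=1e-12)

    def test_score_zero_gives_kmn(self, scheme):
        space = SearchSpace(50, 200)
        assert evalue_of(0, space, scheme) == pytest.approx(
            scheme.k_const * 50 * 200)

    def test_unit_score_ratio_is_exp_lambda(self, scheme):
        space = SearchSpace(100, 100)
        e1, e2 = evalue_of(10, space, scheme), evalue_of(11, space, scheme)
        assert e2 / e1 == pytest.approx(math.exp(-scheme.lam))

    def test_monotone_in_score_and_database_size(self, scheme):
        sp1, sp2 = SearchSpace(100, 1000), SearchSpace(100, 2000)
        assert evalue_of(20, sp1, scheme) > evalue_of(21, sp1, scheme)
        assert evalue_of(20, sp2, scheme) > evalue_of(20, sp1, scheme)

    def test_uncalibrated_scheme_is_an_error(self):
        scheme = ScoringScheme()  # lam unset
        with pytest.raises(CalibrationError):
            evalue_of(10, SearchSpace(10, 10), scheme)

    def test_min_score_for_evalue_is_tight(self, scheme):
        space = SearchSpace(600, 40000)
        s = min_score_for_evalue(1e-5, space, scheme)
        assert evalue_of(s, space, scheme) <= 1e-5
        assert evalue_of(s - 1, space, scheme) > 1e-5
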