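"""TE detection gates, chimera mask-and-requery, inverted repeats."""

import numpy as np
import pytest

from conftest import random_seq
from venomest.align import reverse_complement
from venomest.annotate import ReferenceRecord
from venomest.repeats import (
    IrParams,
    RepeatSearchParams,
    classify_chimera,
    detect_inverted_repeats,
    detect_tes,
    mask_te,
    summarize_te_families,
)

P = RepeatSearchParams()


@pytest.fixture(scope="module")
def te_library():
    rng = np.random.default_rng(321)
    bases = np.array(list("ACGT"))

    def rs(n):
        return "".join(bases[rng.integers(0, 4, n)])

    return [("TE_A", rs(400)), ("TE_B", rs(350))]


class TestDetectTes:
    def test_60bp_copy_in_400nt_passes_all_gates(self, scheme, te_library, rng):
        te = te_library[0][1]
        uni = random_seq(rng, 170) + te[:60] + random_seq(rng, 170)
        anns = detect_tes(uni, te_library, scheme)
        assert len(anns) == 1
        a = anns[0]
        assert a.repeat_id == "TE_A" and a.aligned_length >= 60
        assert a.identity > 0.8 and a.coverage >= 0.10 and a.evalue <= 1e-10

    def test_45bp_copy_fails_length_gate(self, scheme, te_library, rng):
        te = te_library[0][1]
        uni = random_seq(rng, 180) + te[:45] + random_seq(rng, 175)
        assert detect_tes(uni, te_library, scheme) == []

    def test_60bp_copy_in_700nt_fails_coverage_gate(self, scheme, te_library, rng):
        te = te_library[0][1]
        uni = random_seq(rng, 330) + te[:60] + random_seq(rng, 310)
        assert detect_tes(uni, te_library, scheme) == []

    def test_identity_gate_is_strictly_above_80pct(self, scheme, te_library, rng):
        te = te_library[0][1][:300]
        # 60 substitutions spread evenly -> identity exactly 0.80: rejected
        def mutate(seq, k):
            out = list(seq)
            step = len(seq) // k
            for i in range(k):
                p = 2 + i * step
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)

        uni80 = random_seq(rng, 60) + mutate(te, 60) + random_seq(rng, 60)
        anns = detect_tes(uni80, te_library, scheme)
        assert all(not (a.identity <= 0.80) for a in anns)
        uni84 = random_seq(rng, 60) + mutate(te, 48) + random_seq(rng, 60)
        anns = detect_tes(uni84, te_library, scheme)
        assert anns and anns[0].identity > 0.80

    def test_reverse_strand_copy_detected(self, scheme, te_library, rng):
        te = te_library[1][1]
        uni = random_seq(rng, 100) + reverse_complement(te[:80]) + random_seq(rng, 100)
        anns = detect_tes(uni, te_library, scheme)
        assert anns and anns[0].strand == "reverse"

    def test_empty_library_is_error(self, scheme, rng):
        with pytest.raises(ValueError):
            detect_tes(random_seq(rng, 200), [], scheme)


class TestMaskTe:
    def test_mask_preserves_length_and_flanks(self, rng):
        seq = random_seq(rng, 400)
        masked = mask_te(seq, (100, 160))
        assert len(masked) == 400
        assert masked[:100] == seq[:100] and masked[160:] == seq[160:]
        assert masked[100:160] == "N" * 60

    def test_masking_is_idempotent(self, rng):
        seq = random_seq(rng, 300)
        once = mask_te(seq, (50, 120))
        assert mask_te(once, (50, 120)) == once

    def test_out_of_range_interval_is_error(self, rng):
        with pytest.raises(ValueError):
            mask_te("ACGT", (2, 9))


@pytest.fixture(scope="module")
def chimera_parts(te_library):
    rng = np.random.default_rng(99)
    bases = np.array(list("ACGT"))
    host = "".join(bases[rng.integers(0, 4, 900)])
    te = te_library[0][1][:150]
    uni = host[:350] + te  # 500 nt, TE coverage 0.30
    return host, te, uni


class TestClassifyChimera:

    def test_host_hit_over_half_unmasked_is_chimeric(self, scheme, te_library,
                                                     chimera_parts):
        host, te, uni = chimera_parts
        anns = detect_tes(uni, te_library, scheme)
        # host reference exposing 200 nt of the host part -> 200/350 = 0.57
        refs = [ReferenceRecord("HOST", host[75:275], "non_toxin")]
        call, reason = classify_chimera(uni, anns, refs, scheme)
        assert reason == "chimeric" and call is not None
        assert call.host_fraction == pytest.approx(200 / 350, abs=0.02)

    def test_host_hit_below_half_unmasked_is_not_chimeric(self, scheme,
                                                          te_library,
                                                          chimera_parts):
        host, te, uni = chimera_parts
        anns = detect_tes(uni, te_library, scheme)
        refs = [ReferenceRecord("HOST", host[100:250], "non_toxin")]
        call, reason = classify_chimera(uni, anns, refs, scheme)
        assert call is None and reason == "host_fraction_below_minimum"

    def test_te_coverage_095_is_ineligible(self, scheme, te_library, rng):
        te = te_library[0][1]
        uni = random_seq(rng, 20) + te  # coverage ~0.95
        anns = detect_tes(uni, te_library, scheme)
        refs = [ReferenceRecord("HOST", random_seq(rng, 400), "non_toxin")]
        call, reason = classify_chimera(uni, anns, refs, scheme)
        assert call is None and reason == "coverage_out_of_range"

    def test_no_te_annotation_is_ineligible(self, scheme, rng):
        refs = [ReferenceRecord("HOST", random_seq(rng, 400), "non_toxin")]
        call, reason = classify_chimera(random_seq(rng, 300), [], refs, scheme)
        assert call is None and reason == "no_te"


def mutate_positions(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestInvertedRepeats:
    def test_constructed_arm_pair_found_with_exact_coordinates(self, scheme, rng):
        arm = random_seq(rng, 40)
        spacer = random_seq(rng, 20)
        # guard bases prevent chance extension of the arms
        # arms touch the sequence boundaries, so no chance extension
        s = arm + spacer + reverse_complement(arm)
        irs = detect_inverted_repeats(s, scheme)
        assert len(irs) == 1
        ir = irs[0]
        assert (ir.left_start, ir.left_end) == (0, 40)
        assert (ir.right_start, ir.right_end) == (60, 100)
        assert ir.mismatches == 0 and ir.inter_ir_length == 20

    def test_mismatch_fraction_boundary_ten_percent(self, scheme, rng):
        arm = random_seq(rng, 40)
        spacer = random_seq(rng, 30)
        flanks = random_seq(rng, 50), random_seq(rng, 50)
        # evenly spread mismatches in the right arm
        four = mutate_positions(reverse_complement(arm), [4, 13, 22, 31])
        s4 = flanks[0] + arm + spacer + four + flanks[1]
        irs4 = [i for i in detect_inverted_repeats(s4, scheme)
                if i.arm_length >= 35]
        assert irs4 and irs4[0].mismatch_fraction <= 0.10 + 1e-9
        five = mutate_positions(reverse_complement(arm), [4, 12, 20, 28, 36])
        s5 = flanks[0] + arm + spacer + five + flanks[1]
        irs5 = [i for i in detect_inverted_repeats(s5, scheme)
                if i.arm_length >= 35]
        assert irs5 == []

    def test_arm_below_minimum_length_not_reported(self, scheme, rng):
        arm = random_seq(rng, 25)
        s = random_seq(rng, 80) + arm + random_seq(rng, 20) + \
            reverse_complement(arm) + random_seq(rng, 80)
        assert all(i.arm_length >= 30 for i in detect_inverted_repeats(s, scheme))

    def test_random_sequence_has_no_inverted_repeats(self, scheme, rng):
        assert detect_inverted_repeats(random_seq(rng, 800), scheme) == []

    def test_arms_never_overlap_and_fraction_bounded(self, scheme, rng):
        base = random_seq(rng, 700)
        from venomest.simulate import plant_inverted_repeat
        seq, _ = plant_inverted_repeat(base, 100, 60, 30, 0.05, rng)
        seq, _ = plant_inverted_repeat(seq, 500, 45, 80, 0.0, rng)
        for ir in detect_inverted_repeats(seq, scheme):
            assert ir.left_end <= ir.right_start
            assert ir.mismatch_fraction <= 0.10 + 1e-9

    @pytest.mark.parametrize("seed", [3, 4])
    def test_agrees_with_quadratic_bruteforce(self, scheme, seed):
        rng = np.random.default_rng(seed)
        base = random_seq(rng, 500)
        seq, _ = __import__("venomest.simulate", fromlist=["x"]) \
            .plant_inverted_repeat(base, 200, 50, 40, 0.04, rng)
        got = {(i.left_start, i.left_end, i.right_start, i.right_end)
               for i in detect_inverted_repeats(seq, scheme)}
        want = oracle_inverted_repeats(seq, scheme, IrParams())
        assert got == want


def oracle_inverted_repeats(seq, scheme, params):
    """Independent per-diagonal scan with the same stated segment rule."""
    import math

    L = len(seq)
    r = reverse_complement(seq)
    results = set()
    candidates = []
    for d in range(-(L - params.min_arm_length), L - params.min_arm_length + 1):
        i = max(0, d)
        j = i - d
        score = 0
        anchor = i
        best_score, best_end = 0, -1
        path = []
        while i < L and j < L:
            s = scheme.match if (seq[i] == r[j] and seq[i] != "N") \
                else scheme.mismatch
            if score + s <= 0:
                path.append((anchor, best_end, best_score))
                score, anchor, best_score, best_end = 0, i + 1, 0, -1
            else:
                score += s
                if score > best_score:
                    best_score, best_end = score, i
            i += 1
            j += 1
        path.append((anchor, best_end, best_score))
        for a, e, sc in path:
            ln = e - a + 1
            if ln < params.min_arm_length:
                continue
            arm1 = (a, e + 1)
            arm2 = (L - (e + 1 - d), L - (a - d))
            left, right = sorted([arm1, arm2])
            if left[1] > right[0]:
                continue
            mism = sum(1 for x, y in zip(
                seq[left[0]:left[1]],
                reverse_complement(seq[right[0]:right[1]])) if x != y)
            if mism / ln > params.max_mismatch_fraction + 1e-12:
                continue
            ev = (scheme.k_const * L * L * math.exp(-scheme.lam * sc))
            if ev > params.self_alignment_evalue_cutoff:
                continue
            candidates.append((sc, left, right))
    # non-overlapping selection, best score first
    candidates = sorted(set(candidates), key=lambda c: (-c[0], c[1], c[2]))
    kept = []
    for sc, left, right in candidates:
        overlap = any(
            a0 < b1 and b0 < a1
            for a0, a1 in (left, right)
            for _, kl, kr in kept
            for b0, b1 in (kl, kr)
        )
        if not overlap:
            kept.append((sc, left, right))
    return {(l[0], l[1], r0, r1) for _, l, (r0, r1) in kept}


class TestFamilySummary:
    class _Ann:
        def __init__(self, uid, rid, fam):
            self.unisequence_id, self.repeat_id, self.family = uid, rid, fam

    def test_counts_distinct_unisequences_per_family(self):
        anns = [self._Ann("u1", "BovB", "RTE"), self._Ann("u1", "BovB", "RTE"),
                self._Ann("u2", "BovB", "RTE"), self._Ann("u2", "CR1_HS", "CR1")]
        rows = summarize_te_families(anns)
        assert rows[0] == ("RTE", "BovB", 2)
        assert ("CR1", "CR1_HS", 1) in rows

    def test_multifamily_unisequence_counts_once_per_family(self):
        anns = [self._Ann("u1", "BovB", "RTE"), self._Ann("u1", "CR1_HS", "CR1")]
        rows = summarize_te_families(anns)
        total = sum(n for _, _, n in rows)
        assert total == 2  # one unisequence, two family rows
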