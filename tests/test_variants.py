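"""SNP/indel calling rules, synonymy classification, microsatellites."""

import numpy as np
import pytest

from conftest import random_seq
from venomest.align import reverse_complement
from venomest.annotate import Annotation, FrameRecord
from venomest.assembly import Contig, ContigMember, build_unisequences
from venomest.io_utils import Read
from venomest.variants import (
    FRAME_UNKNOWN,
    NONCODING,
    NONSYNONYMOUS,
    SYNONYMOUS,
    MicrosatThresholds,
    SnpParams,
    SNPCall,
    TandemRepeat,
    call_indels,
    call_snps,
    classify_snp,
    exclude_te_overlaps,
    find_microsatellites,
)


def make_contig(columns, plates, quals=None, contig_id="ContigX"):
    """Build a contig from per-read aligned strings (equal length, pads ok)."""
    n_reads = len(columns)
    n_cols = len(columns[0])
    quals = quals or [[30] * n_cols for _ in range(n_reads)]
    members = [
        ContigMember(read_id=f"r{i}", offset=0, strand="forward",
                     aligned=columns[i], quals=tuple(quals[i]),
                     plate=plates[i])
        for i in range(n_reads)
    ]
    col_to_cons = np.arange(n_cols)
    consensus = "".join(
        max("ACGT", key=lambda b: sum(1 for c in columns if c[j] == b))
        for j in range(n_cols)
    )
    return Contig(contig_id=contig_id, consensus=consensus, members=members,
                  col_to_cons=col_to_cons)


def snp_layout(base_seq, col, alleles_plates):
    """Reads identical to base_seq except allele at `col` per read."""
    cols, plates = [], []
    for allele, plate in alleles_plates:
        cols.append(base_seq[:col] + allele + base_seq[col + 1:])
        plates.append(plate)
    return cols, plates


BASE = "ACGTACGTACGTACGTACGTACGTACGT"


class TestCallSnps:
    def test_two_read_contig_is_ineligible(self):
        cols, plates = snp_layout(BASE, 10, [("T", 1), ("C", 2)])
        contig = make_contig(cols, plates)
        assert call_snps(contig) == []

    def test_balanced_alleles_across_plates_yield_one_snp(self):
        cols, plates = snp_layout(BASE, 10, [("T", 1), ("T", 1), ("C", 2), ("C", 2)])
        contig = make_contig(cols, plates)
        calls = call_snps(contig)
        assert len(calls) == 1
        snp = calls[0]
        assert snp.column == 10
        assert {b: n for b, (n, _) in snp.alleles.items()} == {"T": 2, "C": 2}

    def test_single_plate_support_is_rejected(self):
        cols, plates = snp_layout(BASE, 10, [("T", 1), ("T", 1), ("C", 1), ("C", 1)])
        assert call_snps(make_contig(cols, plates)) == []

    def test_low_quality_reads_do_not_support(self):
        cols, plates = snp_layout(BASE, 10, [("T", 1), ("T", 2), ("C", 2), ("C", 3)])
        quals = [[30] * len(BASE) for _ in range(4)]
        quals[2] = [10] * len(BASE)  # one C-read below min quality
        assert call_snps(make_contig(cols, plates, quals)) == []

    def test_minor_allele_below_support_threshold_rejected(self):
        cols, plates = snp_layout(BASE, 10, [("T", 1), ("T", 2), ("T", 3), ("C", 2)])
        assert call_snps(make_contig(cols, plates)) == []

    def test_pad_in_flank_disqualifies_supporting_read(self):
        cols, plates = snp_layout(BASE, 10, [("T", 1), ("T", 1), ("C", 2), ("C", 2)])
        # put a pad 3 columns from the SNP in one T-read
        cols[0] = cols[0][:7] + "-" + cols[0][8:]
        calls = call_snps(make_contig(cols, plates))
        assert calls == []  # T allele support drops to 1

    def test_plate_tags_required(self):
        cols, plates = snp_layout(BASE, 10, [("T", 1), ("T", 1), ("C", 2), ("C", 2)])
        contig = make_contig(cols, plates)
        contig.members[0].plate = None
        with pytest.raises(ValueError):
            call_snps(contig)


class TestCallIndels:
    def test_balanced_one_base_indel(self):
        with_g = BASE[:10] + "G" + BASE[10:]
        with_pad = BASE[:10] + "-" + BASE[10:]
        contig = make_contig([with_g, with_g, with_pad, with_pad], [1, 1, 2, 2])
        calls = call_indels(contig)
        assert len(calls) == 1
        call = calls[0]
        assert (call.col_start, call.col_end) == (10, 11)
        assert call.bases == "G"
        assert call.with_support == 2 and call.without_support == 2

    def test_single_read_pad_not_called(self):
        with_g = BASE[:10] + "G" + BASE[10:]
        with_pad = BASE[:10] + "-" + BASE[10:]
        contig = make_contig([with_g, with_g, with_g, with_pad], [1, 2, 1, 2])
        assert call_indels(contig) == []

    def test_adjacent_pad_columns_are_one_call(self):
        with_gg = BASE[:10] + "GC" + BASE[10:]
        with_pad = BASE[:10] + "--" + BASE[10:]
        contig = make_contig([with_gg, with_gg, with_pad, with_pad], [1, 2, 1, 2])
        calls = call_indels(contig)
        assert len(calls) == 1
        assert (calls[0].col_start, calls[0].col_end) == (10, 12)
        assert calls[0].bases == "GC"


def frame_for(consensus, cds_start, cds_end, strand="forward"):
    if strand == "forward":
        q2s = {i: i for i in range(len(consensus))}
    else:
        q2s = {i: len(consensus) - 1 - i for i in range(len(consensus))}
    return FrameRecord(reference_id="R", strand=strand, cds_start=cds_start,
                       cds_end=cds_end, query_to_subject=q2s,
                       subject_to_query={s: q for q, s in q2s.items()})


def snp_at(pos, alleles):
    return SNPCall(contig_id="C", column=pos, consensus_position=pos,
                   alleles={b: (2, (1, 2)) for b in alleles})


class TestClassifySnp:
    def test_third_position_his_his_is_synonymous(self):
        consensus = "CATGGG"
        frame = frame_for(consensus, 0, 6)
        assert classify_snp(snp_at(2, ["T", "C"]), frame, consensus) == SYNONYMOUS

    def test_second_position_glu_val_is_nonsynonymous(self):
        consensus = "GAAGGG"
        frame = frame_for(consensus, 0, 6)
        assert classify_snp(snp_at(1, ["A", "T"]), frame, consensus) == NONSYNONYMOUS

    def test_outside_cds_is_noncoding(self):
        consensus = "CATGGGTTTT"
        frame = frame_for(consensus, 0, 6)
        assert classify_snp(snp_at(8, ["T", "A"]), frame, consensus) == NONCODING

    def test_symmetric_in_allele_order(self):
        consensus = "GAAGGG"
        frame = frame_for(consensus, 0, 6)
        a = classify_snp(snp_at(1, ["A", "T"]), frame, consensus)
        b = classify_snp(snp_at(1, ["T", "A"]), frame, consensus)
        assert a == b

    def test_unmapped_position_is_frame_unknown(self):
        consensus = "CATGGG"
        frame = frame_for(consensus, 0, 6)
        del frame.query_to_subject[2]
        assert classify_snp(snp_at(2, ["T", "C"]), frame, consensus) == FRAME_UNKNOWN

    def test_no_frame_means_noncoding(self):
        assert classify_snp(snp_at(2, ["T", "C"]), None, "CATGGG") == NONCODING


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------


def oracle_microsatellites(seq, thresholds):
    """Naive tandem scan, written independently: try every (start, motif)."""
    found = set()
    n = len(seq)
    for k in range(1, 7):
        for start in range(n - 2 * k + 1):
            motif = seq[start:start + k]
            # primitive?
            if any(k % d == 0 and motif == motif[:d] * (k // d)
                   for d in range(1, k)):
                continue
            # maximal: must not extend left
            if start >= k and seq[start - k:start] == motif:
                continue
            if start >= 1 and seq[start - 1] == seq[start - 1 + k]:
                continue
            end = start + k
            while end < n and seq[end] == seq[end - k]:
                end += 1
            copies = (end - start) / k
            if copies >= thresholds.min_copies(k):
                canon = min(motif[i:] + motif[:i] for i in range(k))
                found.add((canon, start, end))
    # drop arrays nested inside longer ones
    out = set()
    for item in found:
        _, s, e = item
        if not any(os <= s and e <= oe and (os, oe) != (s, e)
                   for _, os, oe in found):
            out.add(item)
    return out


class TestMicrosatellites:
    def test_trinucleotide_array_found(self, rng):
        left, right = random_seq(rng, 60), random_seq(rng, 60)
        seq = left + "AGC" * 7 + right
        reps = [r for r in find_microsatellites(seq) if len(r.motif) == 3]
        assert any(r.motif == min("AGC", "GCA", "CAG")
                   and r.copies >= 7 for r in reps)

    def test_dinucleotide_below_threshold_not_reported(self, rng):
        seq = random_seq(rng, 50).replace("AT", "GC") + "AT" * 6 + "GG" + \
            random_seq(rng, 50).replace("AT", "GC")
        assert all(r.motif != "AT" for r in find_microsatellites(seq))

    def test_homopolymer_reported_as_mononucleotide(self):
        seq = "GC" * 20 + "A" * 14 + "CG" * 20
        reps = find_microsatellites(
            seq, MicrosatThresholds(mono=12, di=100, tri=100))
        assert len([r for r in reps if "A" * 14 in seq[r.start:r.end]]) == 1
        assert all(len(r.motif) == 1 for r in reps
                   if "A" in r.motif)

    def test_motif_reported_in_canonical_rotation(self, rng):
        seq = random_seq(rng, 40) + "GCA" * 6 + random_seq(rng, 40)
        reps = [r for r in find_microsatellites(seq) if len(r.motif) == 3]
        assert reps and reps[0].motif == "AGC"

    def test_interval_length_consistency(self, rng):
        seq = random_seq(rng, 30) + "AAGG" * 5 + random_seq(rng, 30)
        for r in find_microsatellites(seq):
            assert r.end - r.start == round(r.copies * len(r.motif))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_scanner_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 2000)
        # plant a few arrays so there is something to find
        seq = (seq[:400] + "AT" * 9 + seq[400:900] + "AAC" * 6
               + seq[900:1400] + "A" * 15 + seq[1400:])
        thresholds = MicrosatThresholds()
        got = {(r.motif, r.start, r.end) for r in find_microsatellites(seq, thresholds)}
        want = oracle_microsatellites(seq, thresholds)
        assert got == want


class TestTeExclusion:
    def _repeat(self, uid):
        return TandemRepeat(unisequence_id=uid, motif="AG", copies=8.0,
                            start=0, end=16)

    class _TE:
        def __init__(self, uid):
            self.unisequence_id = uid

    def test_te_bearing_unisequence_excluded(self):
        reps = [self._repeat("u1"), self._repeat("u2")]
        out = exclude_te_overlaps(reps, [self._TE("u1")])
        assert [r.unisequence_id for r in out] == ["u2"]

    def test_empty_te_set_is_identity(self):
        reps = [self._repeat("u1")]
        assert exclude_te_overlaps(reps, []) == reps
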