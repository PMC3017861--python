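"""Transposable-element detection, TE-host chimera classification, and
long inverted-repeat discovery.

TE annotation searches each unisequence (both strands) against a repeat
library and applies four gates: E <= 1e-10, alignment length >= 50 bp,
identity > 80%, and coverage of at least 10% of the unisequence.
Unisequences whose total TE coverage falls strictly between 10% and 90%
are candidate chimeras: the TE is masked with N's and the remainder is
re-queried against a host reference collection; the call is chimeric
when the best host hit involves at least 50% of the unmasked length at
identity >= 70% (the unmasked-length convention is deliberate — a TE at
89% coverage leaves only 11% of the full sequence, which could never
reach a whole-length 50%).

Inverted repeats are found by aligning each sequence against its own
reverse complement.  Arms are gap-free (Hamming mismatches only), at
least 30 bp long by default, with a mismatch fraction of at most 10% and
a self-alignment E-value of at most 1e-5; the trivial self-match and any
arm pair that overlaps itself are excluded.  The spacing between arms is
reported as the inter-IR length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .align import (
    LocalAlignment,
    ScoringScheme,
    SearchSpace,
    encode,
    evalue_of,
    min_score_for_evalue,
    reverse_complement,
    search_both_strands,
)
from .annotate import ReferenceRecord, search_references

__all__ = [
    "RepeatSearchParams",
    "IrParams",
    "TEAnnotation",
    "ChimeraCall",
    "InvertedRepeat",
    "detect_tes",
    "mask_te",
    "classify_chimera",
    "detect_inverted_repeats",
    "summarize_te_families",
]


@dataclass(frozen=True)
class RepeatSearchParams:
    te_evalue_cutoff: float = 1e-10
    te_min_alignment: int = 50
    te_min_identity: float = 0.80  # strict: identity must exceed this
    te_min_coverage: float = 0.10
    chimera_coverage_lo: float = 0.10  # eligibility is the open interval
    chimera_coverage_hi: float = 0.90
    chimera_min_host_fraction: float = 0.50
    chimera_min_host_identity: float = 0.70
    host_evalue_cutoff: float = 1e-5


@dataclass(frozen=True)
class IrParams:
    min_arm_length: int = 30
    max_mismatch_fraction: float = 0.10
    self_alignment_evalue_cutoff: float = 1e-5


@dataclass(frozen=True)
class TEAnnotation:
    unisequence_id: str
    repeat_id: str
    family: str
    q_start: int
    q_end: int
    strand: str
    aligned_length: int
    identity: float
    evalue: float
    coverage: float
    score: int


@dataclass(frozen=True)
class ChimeraCall:
    unisequence_id: str
    te_annotations: tuple
    masked_intervals: tuple
    host_hit: LocalAlignment
    host_fraction: float
    host_identity: float


@dataclass(frozen=True)
class InvertedRepeat:
    unisequence_id: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    mismatches: int
    score: int
    evalue: float

    @property
    def arm_length(self) -> int:
        return self.left_end - self.left_start

    @property
    def mismatch_fraction(self) -> float:
        return self.mismatches / self.arm_length

    @property
    def inter_ir_length(self) -> int:
        return self.right_start - self.left_end


# ---------------------------------------------------------------------------
# TE detection
# ---------------------------------------------------------------------------


def detect_tes(
    sequence: str,
    repeat_library: list[tuple[str, str]],
    scheme: ScoringScheme,
    params: RepeatSearchParams | None = None,
    *,
    families: dict | None = None,
    unisequence_id: str = "seq",
) -> list[TEAnnotation]:
    """Repeat-library search with the four printed gates.

    One annotation per non-overlapping query interval, best score first.
    """
    params = params or RepeatSearchParams()
    if not repeat_library:
        raise ValueError("repeat library is empty")
    n_total = sum(len(s) for _, s in repeat_library)
    space = SearchSpace(len(sequence), n_total)
    floor = min_score_for_evalue(params.te_evalue_cutoff, space, scheme)
    hits = []
    for rid, rseq in repeat_library:
        hits.extend(search_both_strands(
            sequence, rseq, scheme, floor,
            query_id=unisequence_id, subject_id=rid, space=space, max_hits=8,
        ))
    L = len(sequence)
    passing = []
    for a in hits:
        coverage = (a.q_end - a.q_start) / L
        if (a.evalue <= params.te_evalue_cutoff
                and a.aligned_length >= params.te_min_alignment
                and a.identity > params.te_min_identity
                and coverage >= params.te_min_coverage):
            passing.append((a, coverage))
    passing.sort(key=lambda t: (-t[0].score, t[0].q_start, t[0].subject_id))
    out: list[TEAnnotation] = []
    for a, coverage in passing:
        if any(a.q_start < o.q_end and o.q_start < a.q_end for o in out):
            continue
        ann = TEAnnotation(
            unisequence_id=unisequence_id, repeat_id=a.subject_id,
            family=(families or {}).get(a.subject_id, a.subject_id),
            q_start=a.q_start, q_end=a.q_end, strand=a.strand,
            aligned_length=a.aligned_length, identity=a.identity,
            evalue=a.evalue, coverage=coverage, score=a.score,
        )
        # every emitted annotation must satisfy all four printed gates
        assert (ann.evalue <= params.te_evalue_cutoff
                and ann.aligned_length >= params.te_min_alignment
                and ann.identity > params.te_min_identity
                and ann.coverage >= params.te_min_coverage)
        out.append(ann)
    return out


def mask_te(sequence: str, annotation: TEAnnotation | tuple) -> str:
    """Replace the TE interval with N's (length-preserving, idempotent)."""
    if isinstance(annotation, TEAnnotation):
        a, b = annotation.q_start, annotation.q_end
    else:
        a, b = annotation
    if not 0 <= a < b <= len(sequence):
        raise ValueError("mask interval outside sequence")
    return sequence[:a] + "N" * (b - a) + sequence[b:]


def classify_chimera(
    sequence: str,
    te_annotations: list[TEAnnotation],
    host_references: list[ReferenceRecord],
    scheme: ScoringScheme,
    params: RepeatSearchParams | None = None,
    *,
    unisequence_id: str = "seq",
) -> tuple[ChimeraCall | None, str]:
    """Mask-and-requery chimera test.

    Returns (call, reason); the call is None when the unisequence is
    ineligible (TE coverage outside the open 10-90% window) or the masked
    re-query finds no adequate host hit.
    """
    params = params or RepeatSearchParams()
    if not te_annotations:
        return None, "no_te"
    L = len(sequence)
    ivs = sorted((t.q_start, t.q_end) for t in te_annotations)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    te_cov = sum(b - a for a, b in merged) / L
    if not params.chimera_coverage_lo < te_cov < params.chimera_coverage_hi:
        return None, "coverage_out_of_range"
    masked = sequence
    for a, b in merged:
        masked = mask_te(masked, (a, b))
    unmasked_len = L - sum(b - a for a, b in merged)
    hits = search_references(masked, host_references, scheme,
                             params.host_evalue_cutoff,
                             query_id=unisequence_id)
    if not hits:
        return None, "no_host_hit"
    best = hits[0]
    host_fraction = (best.q_end - best.q_start) / unmasked_len
    if host_fraction < params.chimera_min_host_fraction:
        return None, "host_fraction_below_minimum"
    if best.identity < params.chimera_min_host_identity:
        return None, "host_identity_below_minimum"
    return ChimeraCall(
        unisequence_id=unisequence_id,
        te_annotations=tuple(te_annotations),
        masked_intervals=tuple(tuple(m) for m in merged),
        host_hit=best, host_fraction=host_fraction,
        host_identity=best.identity,
    ), "chimeric"


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ir_scan(q, r, match, mismatch, min_len, cap):
    """Ungapped local alignments along every diagonal of q x r.

    Emits one maximal-scoring segment per positive-score excursion:
    (i0, i1, j0, j1, score) in rows of the result, where i indexes q and
    j indexes r.  Segments start and end on matching positions.
    """
    L = q.shape[0]
    res = np.empty((cap, 5), dtype=np.int64)
    cnt = 0
    for d in range(-(L - min_len), L - min_len + 1):
        i = d if d > 0 else 0
        j = i - d
        score = 0
        anchor = i
        best_score = 0
        best_end = -1
        while i < L and j < L:
            if q[i] == r[j] and q[i] < 4:
                s = match
            else:
                s = mismatch
            if score + s <= 0:
                if best_end - anchor + 1 >= min_len and cnt < cap:
                    res[cnt, 0] = anchor
                    res[cnt, 1] = best_end + 1
                    res[cnt, 2] = anchor - d
                    res[cnt, 3] = best_end + 1 - d
                    res[cnt, 4] = best_score
                    cnt += 1
                score = 0
                anchor = i + 1
                best_score = 0
                best_end = -1
            else:
                score += s
                if score > best_score:
                    best_score = score
                    best_end = i
            i += 1
            j += 1
        if best_end - anchor + 1 >= min_len and cnt < cap:
            res[cnt, 0] = anchor
            res[cnt, 1] = best_end + 1
            res[cnt, 2] = anchor - d
            res[cnt, 3] = best_end + 1 - d
            res[cnt, 4] = best_score
            cnt += 1
    return res[:cnt]


def detect_inverted_repeats(
    sequence: str,
    scheme: ScoringScheme,
    params: IrParams | None = None,
    *,
    unisequence_id: str = "seq",
) -> list[InvertedRepeat]:
    """Opposite-strand self-alignment arm pairs.

    Gap-free arms of at least ``min_arm_length`` bases, mismatch fraction
    <= ``max_mismatch_fraction`` (boundary inclusive), self-alignment
    E-value <= cutoff; arms must not overlap (excluding, in particular,
    the trivial full-length self-match); reported non-overlapping, best
    score first.
    """
    params = params or IrParams()
    L = len(sequence)
    if L < 2 * params.min_arm_length:
        return []
    q = encode(sequence)
    r = encode(reverse_complement(sequence))
    segs = _ir_scan(q, r, np.int64(scheme.match), np.int64(scheme.mismatch),
                    np.int64(params.min_arm_length), 8192)
    space = SearchSpace(L, L)
    seen = set()
    candidates = []
    for i0, i1, j0, j1, score in segs:
        arm1 = (int(i0), int(i1))
        # r[j] corresponds to forward position L-1-j
        arm2 = (L - int(j1), L - int(j0))
        left, right = (arm1, arm2) if arm1 <= arm2 else (arm2, arm1)
        if left[1] > right[0]:
            continue  # overlapping arms (includes the trivial self-match)
        key = (left, right)
        if key in seen:
            continue
        seen.add(key)
        arm_len = arm1[1] - arm1[0]
        mism = sum(1 for a, b in zip(sequence[left[0]:left[1]],
                                     reverse_complement(sequence[right[0]:right[1]]))
                   if a != b or a == "N")
        if mism / arm_len > params.max_mismatch_fraction + 1e-12:
            continue
        ev = evalue_of(int(score), space, scheme)
        if ev > params.self_alignment_evalue_cutoff:
            continue
        candidates.append(InvertedRepeat(
            unisequence_id=unisequence_id,
            left_start=left[0], left_end=left[1],
            right_start=right[0], right_end=right[1],
            mismatches=mism, score=int(score), evalue=ev,
        ))
    candidates.sort(key=lambda c: (-c.score, c.left_start, c.right_start))
    out: list[InvertedRepeat] = []
    for c in candidates:
        busy = False
        for o in out:
            for a0, a1 in ((c.left_start, c.left_end), (c.right_start, c.right_end)):
                for b0, b1 in ((o.left_start, o.left_end), (o.right_start, o.right_end)):
                    if a0 < b1 and b0 < a1:
                        busy = True
        if not busy:
            out.append(c)
    return out


def summarize_te_families(
    annotations: list[TEAnnotation], families: dict | None = None
) -> list[tuple[str, str, int]]:
    """(family, repeat name, distinct unisequence count), descending.

    A unisequence with TEs from two families counts once per family.
    """
    per_repeat: dict[tuple[str, str], set] = {}
    for a in annotations:
        fam = (families or {}).get(a.repeat_id, a.family)
        per_repeat.setdefault((fam, a.repeat_id), set()).add(a.unisequence_id)
    rows = [(fam, rid, len(us)) for (fam, rid), us in per_repeat.items()]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows
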