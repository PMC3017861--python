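"""Local alignment engine with Karlin–Altschul E-value statistics.

Every similarity search in the pipeline (vector screening, overlap
detection, reference annotation, repeat-library search, inverted-repeat
self-alignment) goes through the same affine-gap Smith–Waterman
implementation defined here, so scoring behaviour and E-value
classification are consistent across stages.

E-values use the ungapped Karlin–Altschul formula ``E = K·m·n·exp(-λ·S)``
applied to gapped scores.  λ is calibrated from the match/mismatch scores
and the background composition; K is a stored constant.  This is an
approximation (gapped λ/K would require simulation) but the pipeline only
uses E-values to apply coarse cut-offs, and both λ and K can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "SearchSpace",
    "CalibrationError",
    "solve_lambda",
    "smith_waterman",
    "smith_waterman_path",
    "search_both_strands",
    "evalue_of",
    "min_score_for_evalue",
    "reverse_complement",
    "encode",
    "alignment_table",
]

# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------

_LETTERS = "ACGTN"
_ENCODE = np.full(256, 4, dtype=np.int8)  # anything unexpected behaves like N
for _i, _c in enumerate(_LETTERS):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i

_MASK_CODE = 5  # sentinel used internally to forbid re-use of query letters

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


# ---------------------------------------------------------------------------
# Scoring scheme and Karlin–Altschul calibration
# ---------------------------------------------------------------------------


class CalibrationError(ValueError):
    """Raised when no positive Karlin–Altschul λ exists for a scheme."""


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap nucleotide scoring with Karlin–Altschul parameters.

    A gap of length L costs ``gap_open + L * gap_extend`` (both negative).
    ``N`` (and any non-ACGT letter) always scores as a mismatch, against
    anything, including another N.
    """

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    lam: float | None = None
    k_const: float = 0.5
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    @property
    def is_calibrated(self) -> bool:
        return self.lam is not None

    def calibrated(self) -> "ScoringScheme":
        """Return a copy with λ solved for the stored scores/background."""
        return replace(self, lam=solve_lambda(self))

    @property
    def expected_score(self) -> float:
        p = np.asarray(self.background)
        s = np.full((4, 4), float(self.mismatch))
        np.fill_diagonal(s, float(self.match))
        return float(p @ s @ p)

    def score_matrix(self) -> np.ndarray:
        """6x6 int32 matrix over codes A,C,G,T,N,MASK."""
        m = np.full((6, 6), np.int32(self.mismatch))
        for i in range(4):
            m[i, i] = self.match
        m[_MASK_CODE, :] = np.int32(-(10**6))
        m[:, _MASK_CODE] = np.int32(-(10**6))
        return m


def solve_lambda(scheme: ScoringScheme, tol: float = 1e-12) -> float:
    """Solve Σᵢⱼ pᵢ pⱼ exp(λ·sᵢⱼ) = 1 for the unique positive root λ.

    Exists iff the expected per-letter score is negative and a positive
    score is achievable; otherwise raises :class:`CalibrationError`.
    """
    if scheme.expected_score >= 0:
        raise CalibrationError(
            "expected per-letter score is non-negative; no positive λ exists"
        )
    p = np.asarray(scheme.background)
    s = np.full((4, 4), float(scheme.mismatch))
    np.fill_diagonal(s, float(scheme.match))
    pp = np.outer(p, p)

    def f(lam: float) -> float:
        return float(np.sum(pp * np.exp(lam * s))) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - defensive
            raise CalibrationError("failed to bracket λ")
    return float(brentq(f, 1e-12, hi, xtol=tol, rtol=1e-14))


@dataclass(frozen=True)
class SearchSpace:
    """Effective search-space sizes (raw lengths, no edge correction)."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if self.m < 1 or self.n < 1:
            raise ValueError("search space dimensions must be >= 1")


def evalue_of(score: float, space: SearchSpace, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation ``E = K·m·n·exp(-λ·score)``."""
    if scheme.lam is None:
        raise CalibrationError("scheme is not calibrated (λ unset)")
    return scheme.k_const * space.m * space.n * math.exp(-scheme.lam * score)


def min_score_for_evalue(
    cutoff: float, space: SearchSpace, scheme: ScoringScheme
) -> int:
    """Smallest integer score whose E-value is <= ``cutoff``."""
    if scheme.lam is None:
        raise CalibrationError("scheme is not calibrated (λ unset)")
    s = math.log(scheme.k_const * space.m * space.n / cutoff) / scheme.lam
    return max(1, math.ceil(s - 1e-9))


# ---------------------------------------------------------------------------
# Alignment record
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocalAlignment:
    """A scored local alignment in 0-based half-open coordinates.

    Query coordinates always refer to the forward strand of the query;
    ``strand`` records the orientation of the aligned query segment
    relative to the subject.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # "forward" | "reverse"
    aligned_length: int
    matches: int
    mismatches: int
    gap_columns: int
    score: int
    evalue: float = math.inf

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length

    @property
    def query_span(self) -> int:
        return self.q_end - self.q_start

    def __post_init__(self) -> None:
        if self.q_end <= self.q_start or self.s_end <= self.s_start:
            raise ValueError("alignment intervals must be non-empty")
        if self.matches + self.mismatches + self.gap_columns != self.aligned_length:
            raise ValueError("column counts do not sum to aligned_length")


# ---------------------------------------------------------------------------
# Smith–Waterman (affine gaps) with traceback, numba-compiled
# ---------------------------------------------------------------------------

# pointer codes for H: 0 stop, 1 diagonal, 2 from E (gap in query), 3 from F
# E/F pointers: 1 opened from H, 0 extended


@njit(cache=True)
def _sw_fill(q, s, smat, gap_open, gap_extend):
    m = q.shape[0]
    n = s.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), np.int32(-(10**8)), dtype=np.int32)
    F = np.full((m + 1, n + 1), np.int32(-(10**8)), dtype=np.int32)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    go = gap_open + gap_extend  # cost of a length-1 gap
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] + go
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                ptrE[i, j] = 1
            else:
                E[i, j] = e_ext
                ptrE[i, j] = 0
            f_open = H[i - 1, j] + go
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                ptrF[i, j] = 1
            else:
                F[i, j] = f_ext
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + smat[qi, s[j - 1]]
            h = np.int32(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = np.uint8(1)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, ptrH, ptrE, ptrF, best, bi, bj


@njit(cache=True)
def _sw_traceback(q, s, ptrH, ptrE, ptrF, bi, bj):
    """Walk back from (bi, bj); return start cell and column counts.

    Returns (qi0, sj0, matches, mismatches, gap_columns).
    """
    i = bi
    j = bj
    matches = 0
    mismatches = 0
    gaps = 0
    state = 0  # 0 = H, 1 = E, 2 = F
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:  # gap in query, consumes subject
            gaps += 1
            opened = ptrE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:  # gap in subject, consumes query
            gaps += 1
            opened = ptrF[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return i, j, matches, mismatches, gaps


@njit(cache=True)
def _sw_ops(ptrH, ptrE, ptrF, bi, bj):
    """Edit ops of the best path ending at (bi, bj), reversed.

    Op codes: 0 = diagonal (consume both), 1 = gap in query (consume
    subject only), 2 = gap in subject (consume query only).
    """
    i = bi
    j = bj
    ops = np.empty(bi + bj, dtype=np.int8)
    k = 0
    state = 0
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            opened = ptrE[i, j]
            j -= 1
            if opened == 1:
                state = 0
        else:
            ops[k] = 2
            k += 1
            opened = ptrF[i, j]
            i -= 1
            if opened == 1:
                state = 0
    return i, j, ops[:k][::-1].copy()


def smith_waterman_path(
    query: str, subject: str, scheme: ScoringScheme
) -> tuple[int, int, int, int, int, np.ndarray] | None:
    """Best local alignment with its edit path.

    Returns ``(score, q_start, q_end, s_start, s_end, ops)`` where ops is
    an int8 array over the alignment columns (0 = substitution/match,
    1 = gap in query, 2 = gap in subject), or None if no positive score.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    q_codes = encode(query)
    s_codes = encode(subject)
    smat = scheme.score_matrix()
    H, ptrH, ptrE, ptrF, best, bi, bj = _sw_fill(
        q_codes, s_codes, smat, np.int32(scheme.gap_open), np.int32(scheme.gap_extend)
    )
    if best <= 0:
        return None
    qi0, sj0, ops = _sw_ops(ptrH, ptrE, ptrF, bi, bj)
    return int(best), qi0, bi, sj0, bj, ops


def _best_alignment(q_codes, s_codes, scheme, smat):
    H, ptrH, ptrE, ptrF, best, bi, bj = _sw_fill(
        q_codes, s_codes, smat, np.int32(scheme.gap_open), np.int32(scheme.gap_extend)
    )
    if best <= 0:
        return None
    qi0, sj0, matches, mismatches, gaps = _sw_traceback(
        q_codes, s_codes, ptrH, ptrE, ptrF, bi, bj
    )
    return int(best), qi0, bi, sj0, bj, matches, mismatches, gaps


def smith_waterman(
    query: str,
    subject: str,
    scheme: ScoringScheme,
    min_score: int = 1,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    max_hits: int | None = None,
    space: SearchSpace | None = None,
) -> list[LocalAlignment]:
    """All non-overlapping (on the query) local alignments scoring >= min_score.

    The best-scoring alignment is reported first; the covered query
    interval is then masked and the search repeated, so reported hits never
    share query letters.  Hits are sorted by descending score, ties broken
    by smallest q_start then smallest s_start.  E-values are attached when
    ``space`` is given and the scheme is calibrated.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    smat = scheme.score_matrix()
    q_codes = encode(query)
    s_codes = encode(subject)
    hits: list[LocalAlignment] = []
    while True:
        res = _best_alignment(q_codes, s_codes, scheme, smat)
        if res is None:
            break
        score, q0, q1, s0, s1, matches, mismatches, gaps = res
        if score < min_score:
            break
        ev = math.inf
        if space is not None and scheme.is_calibrated:
            ev = evalue_of(score, space, scheme)
        hits.append(
            LocalAlignment(
                query_id=query_id,
                subject_id=subject_id,
                q_start=q0,
                q_end=q1,
                s_start=s0,
                s_end=s1,
                strand="forward",
                aligned_length=matches + mismatches + gaps,
                matches=matches,
                mismatches=mismatches,
                gap_columns=gaps,
                score=score,
                evalue=ev,
            )
        )
        if max_hits is not None and len(hits) >= max_hits:
            break
        q_codes = q_codes.copy()
        q_codes[q0:q1] = _MASK_CODE
    hits.sort(key=lambda a: (-a.score, a.q_start, a.s_start))
    return hits


def search_both_strands(
    query: str,
    subject: str,
    scheme: ScoringScheme,
    min_score: int = 1,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    max_hits: int | None = None,
    space: SearchSpace | None = None,
) -> list[LocalAlignment]:
    """Smith–Waterman on the query and its reverse complement.

    Reverse-strand hits are reported with query coordinates mapped back to
    the forward strand and ``strand="reverse"``.
    """
    fwd = smith_waterman(
        query, subject, scheme, min_score,
        query_id=query_id, subject_id=subject_id, max_hits=max_hits, space=space,
    )
    rev_raw = smith_waterman(
        reverse_complement(query), subject, scheme, min_score,
        query_id=query_id, subject_id=subject_id, max_hits=max_hits, space=space,
    )
    lq = len(query)
    rev = [
        replace(a, q_start=lq - a.q_end, q_end=lq - a.q_start, strand="reverse")
        for a in rev_raw
    ]
    hits = fwd + rev
    hits.sort(key=lambda a: (-a.score, a.q_start, a.s_start))
    return hits


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_TABLE_HEADER = (
    "query\tsubject\tpct_identity\tlength\tmismatches\tgapopen\t"
    "qstart\tqend\tsstart\tsend\tevalue\tscore"
)


def alignment_table(hits: list[LocalAlignment]) -> str:
    """BLAST-tabular-style 12-column TSV with 1-based inclusive coordinates."""
    lines = [_TABLE_HEADER]
    for a in hits:
        lines.append(
            "\t".join(
                [
                    a.query_id,
                    a.subject_id,
                    f"{100.0 * a.identity:.2f}",
                    str(a.aligned_length),
                    str(a.mismatches),
                    str(a.gap_columns),
                    str(a.q_start + 1),
                    str(a.q_end),
                    str(a.s_start + 1),
                    str(a.s_end),
                    f"{a.evalue:.2e}" if math.isfinite(a.evalue) else "NA",
                    str(a.score),
                ]
            )
        )
    return "\n".join(lines) + "\n"
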