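"""EST pre-processing: vector screening, quality and polyA/polyT trimming,
slippage flagging, and the 100-bp minimum-length filter.

Stages run in a fixed order — vector excision first (so contaminant bases
cannot distort quality windows), then quality trimming, then terminal
polyA/polyT removal, then slippage flagging — and reads shorter than
``min_length`` after cleaning are discarded.  Cleaning only ever removes
bases: every retained sequence is a contiguous interval of its input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import ScoringScheme, search_both_strands
from .io_utils import Read

__all__ = [
    "CleaningParams",
    "CleaningReport",
    "trim_quality",
    "screen_vector",
    "trim_polyA_polyT",
    "flag_slippage",
    "clean_pipeline",
]


@dataclass(frozen=True)
class CleaningParams:
    quality_window: int = 20
    quality_threshold: float = 16.0
    vector_min_score: int = 18
    polya_min_run: int = 10
    polya_max_mismatch: int = 1
    slippage_window: int = 50
    slippage_dominance: float = 0.8
    min_length: int = 100


KEPT = "kept"
DISCARDED_SHORT = "discarded_short"
DISCARDED_SLIPPAGE = "discarded_slippage"
DISCARDED_ALL_VECTOR = "discarded_all_vector"


@dataclass
class CleaningReport:
    """Per-read cleaning outcomes and trimmed intervals (with reasons)."""

    outcomes: dict = field(default_factory=dict)  # read_id -> outcome
    trimmed: dict = field(default_factory=dict)  # read_id -> [(start, end, reason)]

    def count(self, outcome: str) -> int:
        return sum(1 for o in self.outcomes.values() if o == outcome)

    @property
    def counts(self) -> dict:
        out = {KEPT: 0, DISCARDED_SHORT: 0, DISCARDED_SLIPPAGE: 0,
               DISCARDED_ALL_VECTOR: 0}
        for o in self.outcomes.values():
            out[o] += 1
        return out

    def to_tsv(self) -> str:
        lines = ["read_id\toutcome\ttrimmed_intervals"]
        for rid in sorted(self.outcomes):
            ivs = ";".join(f"{a}-{b}:{r}" for a, b, r in self.trimmed.get(rid, []))
            lines.append(f"{rid}\t{self.outcomes[rid]}\t{ivs}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------


def trim_quality(read: Read, params: CleaningParams) -> Read:
    """Longest contiguous segment whose every sliding-window mean quality
    meets the threshold.

    Windows of ``quality_window`` bases (or the whole read, if shorter)
    must all average at least ``quality_threshold`` inside the retained
    segment.  A zero-length result is allowed.  Ties go to the leftmost
    longest segment.
    """
    n = len(read)
    if n == 0:
        return read
    w = min(params.quality_window, n)
    q = np.asarray(read.qual, dtype=float)
    csum = np.concatenate([[0.0], np.cumsum(q)])
    means = (csum[w:] - csum[:-w]) / w  # window starting at each position
    good = means >= params.quality_threshold
    best = (0, 0)
    i = 0
    m = good.size
    while i < m:
        if good[i]:
            j = i
            while j + 1 < m and good[j + 1]:
                j += 1
            seg = (i, j + w)  # window starts i..j all good
            if seg[1] - seg[0] > best[1] - best[0]:
                best = seg
            i = j + 1
        i += 1
    return read.slice(*best)


# ---------------------------------------------------------------------------
# Vector screening
# ---------------------------------------------------------------------------


def screen_vector(
    read: Read,
    vector_lib: list[tuple[str, str]],
    scheme: ScoringScheme,
    params: CleaningParams,
) -> tuple[Read, list[tuple[int, int]]]:
    """Excise every read interval aligning to a vector record.

    Intervals with alignment score >= ``vector_min_score`` (either strand)
    are removed; if the remainder is non-contiguous the longest fragment
    is kept.  Returns the trimmed read and the excised intervals.
    """
    if not vector_lib:
        raise ValueError("vector library is empty")
    if len(read) == 0:
        return read, []
    hits = []
    for vid, vseq in vector_lib:
        hits.extend(
            search_both_strands(read.seq, vseq, scheme, params.vector_min_score,
                                query_id=read.id, subject_id=vid)
        )
    if not hits:
        return read, []
    ivs = sorted((a.q_start, a.q_end) for a in hits)
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    # complement -> candidate fragments; keep the longest (leftmost on ties)
    frags = []
    prev = 0
    for a, b in merged:
        if a > prev:
            frags.append((prev, a))
        prev = b
    if prev < len(read):
        frags.append((prev, len(read)))
    if not frags:
        return read.slice(0, 0), [tuple(m) for m in merged]
    start, end = max(frags, key=lambda f: (f[1] - f[0], -f[0]))
    return read.slice(start, end), [tuple(m) for m in merged]


# ---------------------------------------------------------------------------
# polyA / polyT trimming
# ---------------------------------------------------------------------------


def _terminal_run(seq: str, base: str, min_run: int, max_mismatch: int,
                  from_end: bool) -> int:
    """Length of the removable terminal run (0 if none qualifies).

    The run is the longest terminal stretch whose innermost base matches
    and which contains at most ``max_mismatch`` non-matching bases; it
    qualifies if it contains at least ``min_run`` matching bases.
    """
    s = seq[::-1] if from_end else seq
    best = 0
    mismatches = 0
    n_match = 0
    for i, c in enumerate(s):
        if c == base:
            n_match += 1
            if n_match >= min_run:
                best = i + 1
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
    return best


def trim_polyA_polyT(read: Read, params: CleaningParams) -> Read:
    """Remove a 3' polyA and/or 5' polyT terminal run.

    Interior runs are untouched; the removed run must contain at least
    ``polya_min_run`` matching bases and at most ``polya_max_mismatch``
    interior non-matching bases.
    """
    end = len(read)
    cut = _terminal_run(read.seq, "A", params.polya_min_run,
                        params.polya_max_mismatch, from_end=True)
    end -= cut
    head = _terminal_run(read.seq[:end], "T", params.polya_min_run,
                         params.polya_max_mismatch, from_end=False)
    return read.slice(head, end)


# ---------------------------------------------------------------------------
# Slippage flagging
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def flag_slippage(read: Read, params: CleaningParams) -> bool:
    """True iff some window is dominated by one nucleotide or dinucleotide.

    Mononucleotide dominance: the most frequent base covers at least
    ``slippage_dominance`` of the window.  Dinucleotide dominance: some
    two-base unit XY occurs so often that its occurrences cover that
    fraction of the window (2 x occurrence count / window length).
    """
    n = len(read)
    if n == 0:
        return False
    w = min(params.slippage_window, n)
    arr = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    thresh = params.slippage_dominance - 1e-12
    # mononucleotide dominance
    for b in _BASES:
        ind = (arr == ord(b)).astype(float)
        csum = np.concatenate([[0.0], np.cumsum(ind)])
        if ((csum[w:] - csum[:-w]) / w >= thresh).any():
            return True
    # dinucleotide dominance
    if n >= 2:
        w2 = w
        for x in _BASES:
            for y in _BASES:
                if x == y:
                    continue
                occ = ((arr[:-1] == ord(x)) & (arr[1:] == ord(y))).astype(float)
                csum = np.concatenate([[0.0], np.cumsum(occ)])
                if occ.size >= w2 - 1:
                    counts = csum[w2 - 1:] - csum[: occ.size - w2 + 2]
                    if (2.0 * counts / w2 >= thresh).any():
                        return True
                elif occ.size and 2.0 * csum[-1] / n >= thresh:
                    return True
    return False


# ---------------------------------------------------------------------------
# Full cleaning pipeline
# ---------------------------------------------------------------------------


def clean_pipeline(
    reads: list[Read],
    vector_lib: list[tuple[str, str]],
    scheme: ScoringScheme,
    params: CleaningParams | None = None,
) -> tuple[list[Read], CleaningReport]:
    """Vector screen -> quality trim -> polyA/polyT trim -> slippage flag,
    then discard reads shorter than ``min_length`` (strict)."""
    params = params or CleaningParams()
    report = CleaningReport()
    cleaned = []
    for read in reads:
        trimmed_ivs = []
        r, vec_ivs = screen_vector(read, vector_lib, scheme, params)
        trimmed_ivs += [(a, b, "vector") for a, b in vec_ivs]
        if len(r) == 0 and vec_ivs:
            report.outcomes[read.id] = DISCARDED_ALL_VECTOR
            report.trimmed[read.id] = trimmed_ivs
            continue
        before = len(r)
        r = trim_quality(r, params)
        if len(r) != before:
            trimmed_ivs.append((len(r), before, "quality"))
        before = len(r)
        r = trim_polyA_polyT(r, params)
        if len(r) != before:
            trimmed_ivs.append((len(r), before, "polyA/polyT"))
        if flag_slippage(r, params):
            report.outcomes[read.id] = DISCARDED_SLIPPAGE
            report.trimmed[read.id] = trimmed_ivs
            continue
        if len(r) < params.min_length:
            report.outcomes[read.id] = DISCARDED_SHORT
            report.trimmed[read.id] = trimmed_ivs
            continue
        report.outcomes[read.id] = KEPT
        report.trimmed[read.id] = trimmed_ivs
        cleaned.append(r)
    return cleaned, report
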