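"""Similarity-based annotation of unisequences and EST-level abundance.

Each unisequence is searched (both strands) against a labeled reference
collection; it is a *hit* when some alignment reaches E <= 1e-5, and its
class is the class label of the best hit.  Hits are further classified as
coding or 3'UTR-only from the reference's CDS coordinates, and a reading
frame is inferred for coding hits so SNPs can later be called synonymous
or non-synonymous.  Abundance is counted at the EST (read) level — a
contig contributes its member count — and reported against the paper
style's two denominators: all ESTs, and toxin ESTs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import (
    LocalAlignment,
    ScoringScheme,
    SearchSpace,
    min_score_for_evalue,
    reverse_complement,
    search_both_strands,
    smith_waterman_path,
)
from .assembly import Unisequence
from .simulate import TOXIN_CLASSES

__all__ = [
    "ReferenceRecord",
    "Annotation",
    "FrameRecord",
    "ClassAbundance",
    "load_references",
    "search_references",
    "classify_hit_region",
    "infer_frame",
    "annotate_unisequences",
    "summarize_abundance",
]

DEFAULT_EVALUE_CUTOFF = 1e-5

CODING = "coding"
UTR_ONLY = "utr_only"
CODING_UNKNOWN = "coding_unknown"


@dataclass(frozen=True)
class ReferenceRecord:
    """A labeled reference transcript with optional CDS coordinates."""

    id: str
    sequence: str
    class_label: str
    cds_start: int | None = None  # 0-based half-open
    cds_end: int | None = None


def load_references(records: list[tuple[str, str, str]]) -> list[ReferenceRecord]:
    """Parse ``(id, sequence, description)`` triples.

    The description carries ``class=<label>`` and, when known,
    ``cds_start=<int> cds_end=<int>`` tokens (the format written by the
    synthetic reference generator).
    """
    out = []
    for rid, seq, desc in records:
        fields = dict(tok.split("=", 1) for tok in desc.split() if "=" in tok)
        cls = fields.get("class", "non_toxin")
        cs = int(fields["cds_start"]) if "cds_start" in fields else None
        ce = int(fields["cds_end"]) if "cds_end" in fields else None
        out.append(ReferenceRecord(rid, seq.upper(), cls, cs, ce))
    return out


@dataclass(frozen=True)
class FrameRecord:
    """Reading-frame assignment of a unisequence via its best coding hit.

    ``query_to_subject`` maps forward-strand unisequence positions to
    reference positions for substitution columns of the alignment;
    positions inside alignment gaps are absent (frame-unknown).
    """

    reference_id: str
    strand: str
    cds_start: int
    cds_end: int
    query_to_subject: dict
    subject_to_query: dict

    @property
    def offset(self) -> int:
        """Frame offset: codon phase of the first mapped CDS position."""
        for q in sorted(self.query_to_subject):
            s = self.query_to_subject[q]
            if self.cds_start <= s < self.cds_end:
                return (s - self.cds_start) % 3
        return 0


@dataclass
class Annotation:
    unisequence_id: str
    status: str  # "hit" | "no_hit"
    est_count: int
    best_hit: LocalAlignment | None = None
    class_label: str | None = None
    hit_region: str | None = None
    frame: FrameRecord | None = None

    @property
    def is_toxin(self) -> bool:
        return self.class_label in TOXIN_CLASSES


# ---------------------------------------------------------------------------
# Reference search
# ---------------------------------------------------------------------------


def _kmer_set(seq: str, k: int, step: int = 1) -> set:
    out = set()
    for i in range(0, len(seq) - k + 1, step):
        km = seq[i:i + k]
        rc = reverse_complement(km)
        out.add(km if km <= rc else rc)
    return out


class ReferenceIndex:
    """Canonical k-mer prescreen so obvious no-hits skip the alignment."""

    def __init__(self, references: list[ReferenceRecord], k: int = 12):
        self.k = k
        self.kmers = {r.id: _kmer_set(r.sequence, k) for r in references}

    def may_hit(self, seq: str, rid: str) -> bool:
        k = self.k
        kmers = self.kmers[rid]
        for i in range(0, len(seq) - k + 1, 4):
            km = seq[i:i + k]
            rc = reverse_complement(km)
            if (km if km <= rc else rc) in kmers:
                return True
        return False


def search_references(
    sequence: str,
    references: list[ReferenceRecord],
    scheme: ScoringScheme,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    *,
    query_id: str = "query",
    index: ReferenceIndex | None = None,
) -> list[LocalAlignment]:
    """Both-strand search against every reference record.

    The database size ``n`` is the total reference length.  Hits with
    E <= ``evalue_cutoff`` are returned ranked by ascending E-value, then
    descending score, then reference id.
    """
    if not references:
        raise ValueError("reference collection is empty")
    n_total = sum(len(r.sequence) for r in references)
    space = SearchSpace(len(sequence), n_total)
    floor = min_score_for_evalue(evalue_cutoff, space, scheme)
    hits: list[LocalAlignment] = []
    for ref in references:
        if index is not None and not index.may_hit(sequence, ref.id):
            continue
        found = search_both_strands(
            sequence, ref.sequence, scheme, floor,
            query_id=query_id, subject_id=ref.id, max_hits=1, space=space,
        )
        hits.extend(a for a in found if a.evalue <= evalue_cutoff)
    hits.sort(key=lambda a: (a.evalue, -a.score, a.subject_id))
    return hits


def classify_hit_region(hit: LocalAlignment, reference: ReferenceRecord) -> str:
    """'utr_only' iff the subject interval is disjoint from the CDS."""
    if reference.cds_start is None or reference.cds_end is None:
        return CODING_UNKNOWN
    if hit.s_end <= reference.cds_start or hit.s_start >= reference.cds_end:
        return UTR_ONLY
    return CODING


def infer_frame(
    sequence: str, hit: LocalAlignment, reference: ReferenceRecord,
    scheme: ScoringScheme,
) -> FrameRecord | None:
    """Map the aligned interval into reference codon coordinates.

    Recomputes the best alignment path in the hit's orientation and
    records the per-position query<->subject correspondence.  Returns
    None for UTR-only hits or references without a CDS.
    """
    if classify_hit_region(hit, reference) != CODING:
        return None
    if hit.strand == "reverse":
        oriented = reverse_complement(sequence)
    else:
        oriented = sequence
    res = smith_waterman_path(oriented, reference.sequence, scheme)
    if res is None:  # pragma: no cover - a hit implies a positive score
        return None
    _, q0, q1, s0, s1, ops = res
    q2s: dict[int, int] = {}
    qi, sj = q0, s0
    L = len(sequence)
    for op in ops:
        if op == 0:
            fwd_q = qi if hit.strand == "forward" else L - 1 - qi
            q2s[fwd_q] = sj
            qi += 1
            sj += 1
        elif op == 1:
            sj += 1
        else:
            qi += 1
    s2q = {s: q for q, s in q2s.items()}
    return FrameRecord(
        reference_id=reference.id, strand=hit.strand,
        cds_start=reference.cds_start, cds_end=reference.cds_end,
        query_to_subject=q2s, subject_to_query=s2q,
    )


# ---------------------------------------------------------------------------
# Unisequence annotation and abundance
# ---------------------------------------------------------------------------


def annotate_unisequences(
    unisequences: list[Unisequence],
    references: list[ReferenceRecord],
    scheme: ScoringScheme,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    *,
    with_frames: bool = True,
) -> list[Annotation]:
    """Annotate every unisequence against the reference collection."""
    by_id = {r.id: r for r in references}
    index = ReferenceIndex(references)
    out = []
    for u in unisequences:
        hits = search_references(u.sequence, references, scheme, evalue_cutoff,
                                 query_id=u.id, index=index)
        if not hits:
            out.append(Annotation(u.id, "no_hit", u.member_count))
            continue
        best = hits[0]
        ref = by_id[best.subject_id]
        region = classify_hit_region(best, ref)
        frame = (infer_frame(u.sequence, best, ref, scheme)
                 if with_frames and region == CODING else None)
        out.append(Annotation(
            unisequence_id=u.id, status="hit", est_count=u.member_count,
            best_hit=best, class_label=ref.class_label, hit_region=region,
            frame=frame,
        ))
    return out


@dataclass
class ClassAbundance:
    """EST-level composition with the two published denominators."""

    total_ests: int
    hit_ests: int
    toxin_ests: int
    per_class_ests: dict  # class label -> EST count (hits only)
    no_hit_ests: int

    @property
    def hit_pct_of_total(self) -> float:
        return 100.0 * self.hit_ests / self.total_ests if self.total_ests else 0.0

    @property
    def toxin_pct_of_total(self) -> float:
        return 100.0 * self.toxin_ests / self.total_ests if self.total_ests else 0.0

    @property
    def toxin_pct_of_hits(self) -> float:
        return 100.0 * self.toxin_ests / self.hit_ests if self.hit_ests else 0.0

    @property
    def class_pct_of_toxin(self) -> dict:
        if not self.toxin_ests:
            return {}
        return {c: 100.0 * n / self.toxin_ests
                for c, n in self.per_class_ests.items() if c in TOXIN_CLASSES}

    @property
    def class_pct_of_total(self) -> dict:
        if not self.total_ests:
            return {}
        return {c: 100.0 * n / self.total_ests for c, n in self.per_class_ests.items()}


def summarize_abundance(annotations: list[Annotation]) -> ClassAbundance:
    """EST-count composition: each contig weighs in with its member count."""
    total = sum(a.est_count for a in annotations)
    hit = sum(a.est_count for a in annotations if a.status == "hit")
    per_class: dict[str, int] = {}
    toxin = 0
    for a in annotations:
        if a.status != "hit":
            continue
        per_class[a.class_label] = per_class.get(a.class_label, 0) + a.est_count
        if a.is_toxin:
            toxin += a.est_count
    return ClassAbundance(
        total_ests=total, hit_ests=hit, toxin_ests=toxin,
        per_class_ests=per_class, no_hit_ests=total - hit,
    )
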