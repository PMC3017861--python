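"""SNP/indel calling from contig layouts and microsatellite mining.

SNPs are called from the padded multiple alignment of each contig under
artifact-control rules modeled on quality-aware EST SNP callers: a contig
must contain at least three reads, every allele needs at least two
supporting reads of adequate base quality, supporting reads must span at
least two sequencing plates (the library's plate-of-origin control
against sequencing artifacts), and the flanking columns must be pad-free
in the supporting reads.  Called SNPs are classified synonymous /
non-synonymous by substituting each allele into its codon through the
contig's inferred reading frame.

Microsatellites are exact tandem arrays of primitive 1-6 nt motifs with
per-class minimum copy numbers; unisequences that carry a transposable
element annotation are excluded from the microsatellite tally, matching
the sequence-level exclusion used in EST surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .annotate import Annotation, UTR_ONLY, CODING_UNKNOWN
from .assembly import Contig, PAD, Unisequence

__all__ = [
    "SnpParams",
    "SNPCall",
    "IndelCall",
    "TandemRepeat",
    "MicrosatThresholds",
    "call_snps",
    "call_indels",
    "classify_snp",
    "classify_contig_snps",
    "find_microsatellites",
    "mine_microsatellites",
    "exclude_te_overlaps",
]


@dataclass(frozen=True)
class SnpParams:
    min_reads_per_contig: int = 3
    min_distinct_plates: int = 2
    min_allele_support: int = 2
    min_base_quality: int = 20
    gap_free_flank: int = 5
    #: minimum fraction of usable reads an allele must reach; controls
    #: false calls from sequencing errors on deep columns
    min_allele_fraction: float = 0.1


SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
NONCODING = "noncoding"
FRAME_UNKNOWN = "frame_unknown"


@dataclass
class SNPCall:
    contig_id: str
    column: int  # layout column
    consensus_position: int
    alleles: dict  # base -> (support count, sorted plate tuple)
    classification: str = FRAME_UNKNOWN
    codons: dict = field(default_factory=dict)  # base -> (codon, residue)

    @property
    def plates(self) -> set:
        out = set()
        for _, (_, plates) in self.alleles.items():
            out.update(plates)
        return out


@dataclass
class IndelCall:
    contig_id: str
    col_start: int  # layout columns, half-open
    col_end: int
    bases: str  # the inserted/deleted bases (majority spelling)
    with_support: int  # reads carrying the bases
    without_support: int  # reads carrying the deletion
    plates: tuple


def _column_entries(contig: Contig, col: int):
    """(member, char, qual) for members covering a layout column."""
    for m in contig.members:
        at = col - m.offset
        if 0 <= at < len(m.aligned):
            yield m, m.aligned[at], m.quals[at]


def _flanks_gap_free(member, col: int, flank: int) -> bool:
    for c in range(col - flank, col + flank + 1):
        if c == col:
            continue
        at = c - member.offset
        if 0 <= at < len(member.aligned) and member.aligned[at] == PAD:
            return False
    return True


def call_snps(contig: Contig, params: SnpParams | None = None) -> list[SNPCall]:
    """Substitution polymorphisms in a contig layout.

    A column yields a SNP iff the contig has at least
    ``min_reads_per_contig`` members; at least two alleles each have
    ``min_allele_support`` reads of quality >= ``min_base_quality``
    (and at least ``min_allele_fraction`` of the usable reads); the
    supporting reads jointly span ``min_distinct_plates`` plates; and the
    supporting reads are pad-free across ``gap_free_flank`` columns on
    each side.
    """
    params = params or SnpParams()
    if any(m.plate is None for m in contig.members):
        raise ValueError(f"{contig.contig_id}: members lack plate tags")
    if len(contig.members) < params.min_reads_per_contig:
        return []
    calls: list[SNPCall] = []
    for col in range(contig.n_columns):
        cons_pos = int(contig.col_to_cons[col])
        if cons_pos < 0:
            continue
        support: dict[str, list] = {}
        usable = 0
        for m, ch, q in _column_entries(contig, col):
            if ch == PAD or ch == "N" or q < params.min_base_quality:
                continue
            usable += 1
            support.setdefault(ch, []).append(m)
        if usable == 0:
            continue
        alleles = {}
        for base, members in support.items():
            members = [m for m in members
                       if _flanks_gap_free(m, col, params.gap_free_flank)]
            if (len(members) >= params.min_allele_support
                    and len(members) / usable >= params.min_allele_fraction):
                alleles[base] = (len(members),
                                 tuple(sorted({m.plate for m in members})))
        if len(alleles) < 2:
            continue
        plates = set()
        for _, (_, pl) in alleles.items():
            plates.update(pl)
        if len(plates) < params.min_distinct_plates:
            continue
        calls.append(SNPCall(
            contig_id=contig.contig_id, column=col,
            consensus_position=cons_pos, alleles=alleles,
        ))
    return calls


def call_indels(contig: Contig, params: SnpParams | None = None) -> list[IndelCall]:
    """Insertion/deletion polymorphisms from pad runs in the layout.

    A maximal run of pad-containing columns yields one call when both the
    padded (deleted) and unpadded (present) alleles meet the support,
    quality and plate rules across the whole run.
    """
    params = params or SnpParams()
    if any(m.plate is None for m in contig.members):
        raise ValueError(f"{contig.contig_id}: members lack plate tags")
    if len(contig.members) < params.min_reads_per_contig:
        return []
    has_pad = [False] * contig.n_columns
    for m in contig.members:
        for i, ch in enumerate(m.aligned):
            if ch == PAD:
                has_pad[m.offset + i] = True
    calls: list[IndelCall] = []
    col = 0
    while col < contig.n_columns:
        if not has_pad[col]:
            col += 1
            continue
        run_start = col
        while col < contig.n_columns and has_pad[col]:
            col += 1
        run_end = col
        with_members, without_members = [], []
        for m in contig.members:
            a0, a1 = run_start - m.offset, run_end - m.offset
            if a0 < 0 or a1 > len(m.aligned):
                continue  # read does not span the whole run
            chars = m.aligned[a0:a1]
            quals = m.quals[a0:a1]
            if min(quals) < params.min_base_quality:
                continue
            # classify by base content: gap placement inside the run is
            # ambiguous in a progressive layout, so any read carrying
            # bases in the run holds the insertion allele
            if all(c == PAD for c in chars):
                without_members.append(m)
            else:
                with_members.append(m)
        usable = len(with_members) + len(without_members)
        if usable == 0:
            continue
        ok = True
        for group in (with_members, without_members):
            if (len(group) < params.min_allele_support
                    or len(group) / usable < params.min_allele_fraction):
                ok = False
        if not ok:
            continue
        plates = {m.plate for m in with_members} | {m.plate for m in without_members}
        if len(plates) < params.min_distinct_plates:
            continue
        spellings: dict[str, int] = {}
        for m in with_members:
            s = m.aligned[run_start - m.offset:run_end - m.offset].replace(PAD, "")
            spellings[s] = spellings.get(s, 0) + 1
        bases = sorted(spellings, key=lambda s: (-spellings[s], s))[0]
        calls.append(IndelCall(
            contig_id=contig.contig_id, col_start=run_start, col_end=run_end,
            bases=bases, with_support=len(with_members),
            without_support=len(without_members), plates=tuple(sorted(plates)),
        ))
    return calls


# ---------------------------------------------------------------------------
# Synonymous / non-synonymous classification
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def classify_snp(snp: SNPCall, frame, consensus: str) -> str:
    """Classify a SNP through an inferred reading frame.

    Substitutes each allele into its codon (standard genetic code):
    identical residues -> synonymous, differing -> nonsynonymous; outside
    the CDS -> noncoding; positions unmappable through alignment gaps ->
    frame_unknown.  Symmetric in allele order.
    """
    if frame is None:
        return NONCODING
    p = snp.consensus_position
    s = frame.query_to_subject.get(p)
    if s is None:
        return FRAME_UNKNOWN
    if not frame.cds_start <= s < frame.cds_end:
        return NONCODING
    phase = (s - frame.cds_start) % 3
    codon_q = []
    for slot in range(3):
        sp = s - phase + slot
        if sp == s:
            codon_q.append(None)  # the SNP slot itself
            continue
        qp = frame.subject_to_query.get(sp)
        if qp is None:
            return FRAME_UNKNOWN
        codon_q.append(qp)
    residues = set()
    snp.codons.clear()
    for allele in sorted(snp.alleles):
        codon = ""
        for slot in range(3):
            if codon_q[slot] is None:
                base = allele
            else:
                base = consensus[codon_q[slot]]
            if frame.strand == "reverse":
                base = _COMP.get(base, "N")
            codon += base
        aa = str(Seq(codon).translate())
        snp.codons[allele] = (codon, aa)
        residues.add(aa)
    return SYNONYMOUS if len(residues) == 1 else NONSYNONYMOUS


def classify_contig_snps(
    snps: list[SNPCall], annotation: Annotation | None, consensus: str
) -> None:
    """Classify every SNP of a contig in place via its annotation."""
    if annotation is None:
        raise ValueError("contig has no annotation; cannot classify SNPs")
    for snp in snps:
        if annotation.status == "no_hit" or annotation.hit_region in (
                UTR_ONLY, CODING_UNKNOWN):
            snp.classification = (NONCODING if annotation.status == "hit"
                                  else FRAME_UNKNOWN)
        else:
            snp.classification = classify_snp(snp, annotation.frame, consensus)


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MicrosatThresholds:
    """Minimum copy numbers per motif length (1..6)."""

    mono: int = 12
    di: int = 7
    tri: int = 5
    tetra: int = 4
    penta: int = 4
    hexa: int = 4

    def min_copies(self, k: int) -> int:
        return (self.mono, self.di, self.tri, self.tetra, self.penta, self.hexa)[k - 1]


@dataclass(frozen=True)
class TandemRepeat:
    unisequence_id: str
    motif: str  # canonical (lexicographically smallest) rotation
    copies: float
    start: int
    end: int


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def _canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_microsatellites(
    sequence: str,
    thresholds: MicrosatThresholds | None = None,
    unisequence_id: str = "seq",
) -> list[TandemRepeat]:
    """Exact tandem arrays of primitive 1-6 nt motifs.

    Maximal arrays only; the motif is reported in its canonical rotation;
    arrays nested inside a longer reported array are dropped.
    """
    thresholds = thresholds or MicrosatThresholds()
    n = len(sequence)
    found: list[TandemRepeat] = []
    for k in range(1, 7):
        if n < 2 * k:
            continue
        j = 0
        limit = n - k
        while j < limit:
            if sequence[j] != sequence[j + k]:
                j += 1
                continue
            r0 = j
            while j < limit and sequence[j] == sequence[j + k]:
                j += 1
            # tandem array occupies [r0, j + k)
            start, end = r0, j + k
            motif = sequence[start:start + k]
            if not _is_primitive(motif):
                continue
            copies = (end - start) / k
            if copies >= thresholds.min_copies(k):
                found.append(TandemRepeat(
                    unisequence_id=unisequence_id,
                    motif=_canonical_rotation(motif),
                    copies=copies, start=start, end=end,
                ))
    found.sort(key=lambda t: (-(t.end - t.start), len(t.motif), t.start))
    kept: list[TandemRepeat] = []
    for t in found:
        if not any(o.start <= t.start and t.end <= o.end for o in kept):
            kept.append(t)
    kept.sort(key=lambda t: (t.start, len(t.motif)))
    return kept


def mine_microsatellites(
    unisequences: list[Unisequence],
    thresholds: MicrosatThresholds | None = None,
) -> list[TandemRepeat]:
    out = []
    for u in unisequences:
        out.extend(find_microsatellites(u.sequence, thresholds, u.id))
    return out


def exclude_te_overlaps(repeats: list[TandemRepeat], te_annotations) -> list[TandemRepeat]:
    """Drop microsatellites on unisequences carrying any TE annotation.

    Exclusion is at the whole-unisequence level (not base overlap),
    matching the convention of counting "sequences with microsatellite
    regions" after removing TE-annotated sequences.
    """
    te_ids = {t.unisequence_id for t in te_annotations}
    return [r for r in repeats if r.unisequence_id not in te_ids]
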