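"""Overlap clustering and greedy consensus assembly of cleaned ESTs.

Reads are clustered by transitive closure over accepted pairwise overlaps
(>= 100 bp at >= 95% identity, either orientation) and each cluster is
assembled progressively, best overlaps first, into a padded layout with a
quality-weighted consensus.  Reads with no accepted overlap stay
singletons.  Contigs plus singletons are the unisequences every later
stage annotates and mines.

This is a deliberately simple greedy assembler, not a CAP3
re-implementation: it preserves the published overlap criteria and the
contig/singleton semantics, not any legacy tool's exact output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import (
    ScoringScheme,
    reverse_complement,
    smith_waterman,
    smith_waterman_path,
)
from .io_utils import Read

__all__ = [
    "AssemblyParams",
    "Overlap",
    "ContigMember",
    "Contig",
    "Unisequence",
    "detect_overlap",
    "cluster_reads",
    "assemble_cluster",
    "build_unisequences",
]

PAD = "-"


@dataclass(frozen=True)
class AssemblyParams:
    """Published overlap criteria plus indexing knobs."""

    min_overlap: int = 100
    min_identity: float = 0.95
    kmer_size: int = 14
    minimizer_window: int = 12

    @property
    def min_overlap_score(self) -> int:
        # score of a minimally acceptable overlap under the active scheme
        # is checked downstream; this is only a pre-filter floor
        return self.min_overlap // 2


@dataclass(frozen=True)
class Overlap:
    """An accepted pairwise overlap (b's coordinates on its forward strand)."""

    a_id: str
    b_id: str
    strand: str  # orientation of b relative to a
    score: int
    identity: float
    aligned_length: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int


def detect_overlap(
    a: Read, b: Read, scheme: ScoringScheme, params: AssemblyParams | None = None
) -> Overlap | None:
    """Best local alignment of two reads; accepted iff it spans at least
    ``min_overlap`` columns at identity >= ``min_identity``.

    Both orientations of ``b`` are tried.  Identity is computed over the
    overlap alignment, not the whole reads.
    """
    params = params or AssemblyParams()
    floor = params.min_overlap_score
    best = None
    for strand, bseq in (("forward", b.seq), ("reverse", reverse_complement(b.seq))):
        hits = smith_waterman(a.seq, bseq, scheme, floor, max_hits=1)
        if hits and (best is None or hits[0].score > best[1].score):
            best = (strand, hits[0])
    if best is None:
        return None
    strand, aln = best
    if aln.aligned_length < params.min_overlap or aln.identity < params.min_identity:
        return None
    if strand == "forward":
        b0, b1 = aln.s_start, aln.s_end
    else:
        b0, b1 = len(b) - aln.s_end, len(b) - aln.s_start
    return Overlap(
        a_id=a.id, b_id=b.id, strand=strand, score=aln.score,
        identity=aln.identity, aligned_length=aln.aligned_length,
        a_start=aln.q_start, a_end=aln.q_end, b_start=b0, b_end=b1,
    )


# ---------------------------------------------------------------------------
# Clustering (union-find over accepted overlaps, k-mer candidate pairs)
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        self.parent[self.find(x)] = self.find(y)


def _minimizers(seq: str, k: int, w: int):
    """Canonical (k, w)-minimizers: (position, canonical k-mer, flipped).

    Every window of w consecutive k-mers contributes its lexicographically
    smallest canonical k-mer, so any exact stretch of k + w - 1 bases
    shared by two reads yields a shared sampled k-mer regardless of the
    reads\' relative phase.
    """
    n = len(seq)
    if n < k:
        return []
    kmers = []
    for p in range(n - k + 1):
        km = seq[p:p + k]
        rc = reverse_complement(km)
        kmers.append((km, False) if km <= rc else (rc, True))
    out = []
    last = -1
    deque_idx: list[int] = []  # monotone increasing canonical k-mers
    for p in range(len(kmers)):
        while deque_idx and kmers[deque_idx[-1]][0] >= kmers[p][0]:
            deque_idx.pop()
        deque_idx.append(p)
        start = p - w + 1
        while deque_idx[0] < start:
            deque_idx.pop(0)
        if p >= w - 1 or p == len(kmers) - 1:
            m = deque_idx[0]
            if m != last:
                canon, flipped = kmers[m]
                out.append((m, canon, flipped))
                last = m
    return out


def _candidate_pairs(reads: list[Read], params: AssemblyParams):
    """Minimizer buckets: canonical k-mer -> [(read, position, flipped)].

    A shared sampled k-mer fixes a relative diagonal; pairs whose implied
    overlap on that diagonal is shorter than ``min_overlap`` cannot
    satisfy the acceptance rule with substitution-dominated errors and
    are skipped cheaply by the caller.
    """
    buckets: dict[str, list[tuple[int, int, bool]]] = {}
    for idx, read in enumerate(reads):
        seen = set()
        for pos, canon, flipped in _minimizers(read.seq, params.kmer_size,
                                               params.minimizer_window):
            if canon in seen:
                continue
            seen.add(canon)
            buckets.setdefault(canon, []).append((idx, pos, flipped))
    return buckets


def cluster_reads(
    reads: list[Read],
    scheme: ScoringScheme,
    params: AssemblyParams | None = None,
) -> tuple[list[list[Read]], list[Overlap]]:
    """Partition reads by transitive closure over accepted overlaps.

    Returns the clusters (ordered by smallest member id, each cluster's
    reads sorted by id) and every accepted overlap found.  The k-mer index
    only proposes candidate pairs; acceptance is always decided by
    :func:`detect_overlap`'s alignment gates.
    """
    params = params or AssemblyParams()
    reads = sorted(reads, key=lambda r: r.id)
    n = len(reads)
    uf = _UnionFind(n)
    overlaps: list[Overlap] = []
    decided: set[tuple[int, int]] = set()
    buckets = _candidate_pairs(reads, params)
    k = params.kmer_size

    for canon in sorted(buckets):
        members = buckets[canon]
        if len(members) < 2:
            continue
        for x in range(len(members)):
            i, pi, fi = members[x]
            for y in range(x + 1, len(members)):
                j, pj, fj = members[y]
                if i == j:
                    continue
                a, b = (i, j) if i < j else (j, i)
                if (a, b) in decided or uf.find(i) == uf.find(j):
                    continue
                # implied overlap from the shared k-mer's diagonal
                la, lb = len(reads[i]), len(reads[j])
                if fi == fj:
                    qj = pj
                else:
                    qj = lb - pj - k
                d = pi - qj
                implied = min(la, lb + d) - max(0, d)
                if implied < params.min_overlap:
                    continue
                decided.add((a, b))
                ov = detect_overlap(reads[a], reads[b], scheme, params)
                if ov is not None:
                    overlaps.append(ov)
                    uf.union(a, b)

    groups: dict[int, list[Read]] = {}
    for idx, read in enumerate(reads):
        groups.setdefault(uf.find(idx), []).append(read)
    clusters = sorted(groups.values(), key=lambda g: g[0].id)
    return clusters, overlaps


# ---------------------------------------------------------------------------
# Progressive consensus assembly
# ---------------------------------------------------------------------------


@dataclass
class ContigMember:
    read_id: str
    offset: int  # first layout column covered
    strand: str  # orientation of the stored (layout-oriented) read
    aligned: str  # read bases in layout orientation, with pads
    quals: tuple  # per-column qualities (pads carry a flanking-average)
    plate: int


@dataclass
class Contig:
    contig_id: str
    consensus: str
    members: list
    col_to_cons: np.ndarray  # layout column -> consensus position (-1 dropped)

    @property
    def n_columns(self) -> int:
        return len(self.col_to_cons)

    def depth(self) -> np.ndarray:
        d = np.zeros(self.n_columns, dtype=int)
        for m in self.members:
            d[m.offset:m.offset + len(m.aligned)] += 1
        return d


@dataclass(frozen=True)
class Unisequence:
    id: str
    kind: str  # "contig" | "singleton"
    sequence: str
    member_read_ids: tuple
    contig: Contig | None = None

    @property
    def member_count(self) -> int:
        return len(self.member_read_ids)


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_IDX_BASE = "ACGTN"


class _Layout:
    """Growing padded multiple alignment with quality-weight columns."""

    def __init__(self):
        self.weights = np.zeros((6, 0), dtype=float)  # A C G T N pad
        self.members: list[list] = []  # [read, offset, strand, chars, quals]

    @property
    def n_cols(self) -> int:
        return self.weights.shape[1]

    def consensus(self) -> tuple[str, np.ndarray]:
        """Quality-weighted consensus and column->consensus mapping.

        Per column the base with the largest cumulative quality wins; ties
        break lexicographically (A<C<G<T<N).  A column where pads outweigh
        every base is dropped from the consensus.
        """
        if self.n_cols == 0:
            return "", np.zeros(0, dtype=int)
        w = self.weights
        best = np.argmax(w[:5], axis=0)  # first max = lexicographic tie-break
        bestw = w[:5].max(axis=0)
        keep = (bestw >= w[5]) & (bestw > 0)
        mapping = np.full(self.n_cols, -1, dtype=int)
        mapping[keep] = np.arange(int(keep.sum()))
        cons = "".join(_IDX_BASE[b] for b, k in zip(best, keep) if k)
        return cons, mapping

    def _insert_column(self, col: int) -> None:
        self.weights = np.insert(self.weights, col, 0.0, axis=1)
        for m in self.members:
            if m[1] >= col:
                m[1] += 1
            elif m[1] < col < m[1] + len(m[3]):
                at = col - m[1]
                m[3].insert(at, PAD)
                q = (m[4][at - 1] if at > 0 else 0) if m[4] else 0
                m[4].insert(at, q)
                self.weights[5, col] += q

    def _grow(self, left: int, right: int) -> None:
        if right > 0:
            self.weights = np.pad(self.weights, ((0, 0), (0, right)))
        if left > 0:
            self.weights = np.pad(self.weights, ((0, 0), (left, 0)))
            for m in self.members:
                m[1] += left

    def add_read(self, read: Read, strand: str, chars: list, quals: list,
                 offset: int) -> None:
        self.members.append([read, offset, strand, chars, quals])
        for c, q, col in zip(chars, quals, range(offset, offset + len(chars))):
            self.weights[_BASE_IDX.get(c, 4) if c != PAD else 5, col] += q

    def finalize(self, contig_id: str) -> Contig:
        cons, mapping = self.consensus()
        members = [
            ContigMember(
                read_id=m[0].id, offset=m[1], strand=m[2],
                aligned="".join(m[3]), quals=tuple(m[4]), plate=m[0].plate,
            )
            for m in sorted(self.members, key=lambda m: (m[1], m[0].id))
        ]
        return Contig(contig_id=contig_id, consensus=cons, members=members,
                      col_to_cons=mapping)


def _oriented(read: Read, strand: str) -> tuple[str, tuple]:
    if strand == "forward":
        return read.seq, read.qual
    return reverse_complement(read.seq), read.qual[::-1]


def _place_read(layout: _Layout, read: Read, strand: str,
                scheme: ScoringScheme, params: AssemblyParams) -> bool:
    """Align the oriented read to the current consensus and add it.

    The aligned interval must meet the overlap gates (length, identity);
    unaligned read tips are placed diagonally, growing the layout when
    the read overhangs it.  Returns False, leaving the layout untouched,
    when no acceptable placement exists.
    """
    seq, qual = _oriented(read, strand)
    if layout.n_cols == 0:
        layout._grow(0, len(seq))
        layout.add_read(read, strand, list(seq), list(qual), 0)
        return True
    cons, mapping = layout.consensus()
    res = smith_waterman_path(seq, cons, scheme)
    if res is None:
        return False
    score, q0, q1, s0, s1, ops = res
    matches = 0
    qi, sj = q0, s0
    for op in ops:
        if op == 0:
            if seq[qi] == cons[sj] and seq[qi] != "N":
                matches += 1
            qi += 1
            sj += 1
        elif op == 1:
            sj += 1
        else:
            qi += 1
    aligned_len = len(ops)
    if (aligned_len < min(params.min_overlap, len(seq))
            or matches / aligned_len < params.min_identity):
        return False

    cons_to_col = np.flatnonzero(mapping >= 0)
    col_s0 = int(cons_to_col[s0])
    col_last = int(cons_to_col[s1 - 1])
    tail = len(seq) - q1
    grow_left = max(0, q0 - col_s0)
    grow_right = max(0, tail - (layout.n_cols - col_last - 1))
    if grow_left or grow_right:
        layout._grow(grow_left, grow_right)
        cons_to_col = cons_to_col + grow_left
        col_s0 += grow_left

    out_chars: list = []
    out_quals: list = []
    start_col = col_s0 - q0
    for t in range(q0):  # leading tip, diagonal placement
        out_chars.append(seq[t])
        out_quals.append(qual[t])
    qi, sj = q0, s0
    cur_col = col_s0
    n_ins = 0
    pending_inserts: list[int] = []  # absolute column indices, final numbering
    for op in ops:
        if op == 2:  # read insertion -> new layout column
            pending_inserts.append(start_col + len(out_chars))
            out_chars.append(seq[qi])
            out_quals.append(qual[qi])
            qi += 1
            n_ins += 1
            cur_col += 1
            continue
        target = int(cons_to_col[sj]) + n_ins
        while cur_col < target:  # pad through dropped layout columns
            out_chars.append(PAD)
            out_quals.append(out_quals[-1] if out_quals else 0)
            cur_col += 1
        if op == 0:
            out_chars.append(seq[qi])
            out_quals.append(qual[qi])
            qi += 1
        else:
            out_chars.append(PAD)
            out_quals.append(out_quals[-1] if out_quals else 0)
        sj += 1
        cur_col += 1
    for t in range(q1, len(seq)):  # trailing tip
        out_chars.append(seq[t])
        out_quals.append(qual[t])

    for at in pending_inserts:
        layout._insert_column(at)
    layout.add_read(read, strand, out_chars, out_quals, start_col)
    return True


def assemble_cluster(
    cluster: list[Read],
    edges: list[Overlap],
    scheme: ScoringScheme,
    params: AssemblyParams | None = None,
    contig_ids=None,
) -> tuple[list[Contig], list[Read]]:
    """Greedy progressive assembly of one overlap cluster.

    Reads are placed in descending order of their best accepted overlap to
    an already-placed read; each placement is re-validated against the
    current consensus.  Reads that cannot be placed consistently are split
    off and assembled recursively, so one input cluster can yield several
    contigs (plus leftover singletons).
    """
    params = params or AssemblyParams()
    if contig_ids is None:
        contig_ids = iter(f"Contig{i}" for i in range(1, 10**6))
    cluster = sorted(cluster, key=lambda r: r.id)
    by_id = {r.id: r for r in cluster}
    adj: dict[str, list[Overlap]] = {r.id: [] for r in cluster}
    for ov in edges:
        if ov.a_id in by_id and ov.b_id in by_id:
            adj[ov.a_id].append(ov)
            adj[ov.b_id].append(ov)

    contigs: list[Contig] = []
    leftovers: list[Read] = []
    unplaced = set(by_id)

    while unplaced:
        # seed: endpoint of the best remaining edge, else a lone read
        cand = [ov for rid in unplaced for ov in adj[rid]
                if ov.a_id in unplaced and ov.b_id in unplaced]
        if not cand:
            leftovers.extend(by_id[rid] for rid in sorted(unplaced))
            break
        cand.sort(key=lambda o: (-o.score, o.a_id, o.b_id))
        seed_edge = cand[0]
        layout = _Layout()
        strands = {seed_edge.a_id: "forward"}
        _place_read(layout, by_id[seed_edge.a_id], "forward", scheme, params)
        placed = {seed_edge.a_id}
        unplaced.discard(seed_edge.a_id)
        failed: set[str] = set()

        while True:
            frontier = [
                ov for rid in placed for ov in adj[rid]
                if (ov.a_id in unplaced) != (ov.b_id in unplaced)
            ]
            frontier = [ov for ov in frontier
                        if (ov.a_id if ov.a_id in unplaced else ov.b_id) not in failed]
            if not frontier:
                break
            frontier.sort(key=lambda o: (-o.score, o.a_id, o.b_id))
            ov = frontier[0]
            new_id, anchor_id = ((ov.a_id, ov.b_id) if ov.a_id in unplaced
                                 else (ov.b_id, ov.a_id))
            anchor_strand = strands[anchor_id]
            if ov.strand == "reverse":
                strand = "reverse" if anchor_strand == "forward" else "forward"
            else:
                strand = anchor_strand
            if _place_read(layout, by_id[new_id], strand, scheme, params):
                strands[new_id] = strand
                placed.add(new_id)
                unplaced.discard(new_id)
            else:
                # try the opposite orientation before giving up
                other = "reverse" if strand == "forward" else "forward"
                if _place_read(layout, by_id[new_id], other, scheme, params):
                    strands[new_id] = other
                    placed.add(new_id)
                    unplaced.discard(new_id)
                else:
                    failed.add(new_id)

        if len(placed) >= 2:
            contigs.append(layout.finalize(next(contig_ids)))
        else:
            leftovers.extend(by_id[rid] for rid in sorted(placed))

    return contigs, leftovers


def build_unisequences(
    reads: list[Read],
    scheme: ScoringScheme,
    params: AssemblyParams | None = None,
) -> list[Unisequence]:
    """Cluster and assemble cleaned reads into contigs + singletons.

    Every read ends up in exactly one unisequence; contigs are listed
    first (Contig1, Contig2, ... in cluster order), then singletons named
    after their read.
    """
    params = params or AssemblyParams()
    clusters, overlaps = cluster_reads(reads, scheme, params)
    counter = iter(f"Contig{i}" for i in range(1, 10**6))
    out: list[Unisequence] = []
    singles: list[Read] = []
    for cluster in clusters:
        if len(cluster) == 1:
            singles.append(cluster[0])
            continue
        contigs, leftovers = assemble_cluster(cluster, overlaps, scheme, params,
                                              contig_ids=counter)
        for c in contigs:
            out.append(Unisequence(
                id=c.contig_id, kind="contig", sequence=c.consensus,
                member_read_ids=tuple(m.read_id for m in c.members), contig=c,
            ))
        singles.extend(leftovers)
    for r in sorted(singles, key=lambda r: r.id):
        out.append(Unisequence(
            id=f"Singleton_{r.id}", kind="singleton", sequence=r.seq,
            member_read_ids=(r.id,),
        ))
    return out
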