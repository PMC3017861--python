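"""Read container and FASTA/QUAL input-output helpers (Biopython-backed)."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Read", "read_fasta", "write_fasta", "read_fasta_qual", "write_fasta_qual"]


@dataclass(frozen=True)
class Read:
    """A single-pass EST: bases, per-base PHRED qualities, plate of origin."""

    id: str
    seq: str
    qual: tuple[int, ...]
    plate: int = 1

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.id}: quality length != sequence length")

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> "Read":
        return replace(self, seq=self.seq[start:end], qual=self.qual[start:end])


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                descriptions: dict[str, str] | None = None) -> None:
    recs = []
    for rid, seq in records:
        desc = (descriptions or {}).get(rid, "")
        recs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(recs, str(path), "fasta")


def _plate_of(description: str) -> int:
    for token in description.split():
        if token.startswith("plate="):
            return int(token.split("=", 1)[1])
    return 1


def read_fasta_qual(fasta_path: str | Path, qual_path: str | Path) -> list[Read]:
    """Load reads from a FASTA file and its PHRED .qual sidecar.

    The plate of origin is taken from a ``plate=<int>`` token in the FASTA
    description line (defaulting to 1).
    """
    quals = {rec.id: tuple(rec.letter_annotations["phred_quality"])
             for rec in SeqIO.parse(str(qual_path), "qual")}
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in quals:
            raise ValueError(f"no qualities for read {rec.id}")
        reads.append(Read(id=rec.id, seq=str(rec.seq).upper(),
                          qual=quals[rec.id], plate=_plate_of(rec.description)))
    return reads


def write_fasta_qual(reads: Iterable[Read], fasta_path: str | Path,
                     qual_path: str | Path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description=f"plate={r.plate}")
        rec.letter_annotations["phred_quality"] = list(r.qual)
        recs.append(rec)
    SeqIO.write(recs, str(fasta_path), "fasta")
    SeqIO.write(recs, str(qual_path), "qual")
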