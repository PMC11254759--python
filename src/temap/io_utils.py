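"""Sequence containers and standard-format I/O.

FASTA/FASTQ parsing and writing go through Biopython's SeqIO; the pipeline
works internally on lightweight :class:`SeqRead` records (sequence plus
integer Phred qualities) to keep the hot loops cheap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters beyond ACGTN are
    complemented via Biopython when present)."""
    if set(seq) <= set("ACGTNacgtn"):
        return seq.translate(_COMPLEMENT)[::-1]
    return str(Seq(seq).reverse_complement())


@dataclass(slots=True)
class SeqRead:
    """A single-end read: identifier, sequence and per-base Phred qualities."""

    id: str
    seq: str
    qual: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.qual:
            self.qual = [30] * len(self.seq)
        if len(self.qual) != len(self.seq):
            raise ValueError(f"quality length mismatch for read {self.id}")

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> "SeqRead":
        return SeqRead(self.id, self.seq[start:end], self.qual[start:end])

    def revcomp(self) -> "SeqRead":
        return SeqRead(self.id, revcomp(self.seq), self.qual[::-1])


def read_fastq(path: str | Path) -> list[SeqRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            SeqRead(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])
        )
    return reads


def write_fastq(reads: Iterable[SeqRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qual)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Ordered name -> sequence mapping (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
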