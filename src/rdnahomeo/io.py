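"""Sequence containers and plain-text I/O (FASTA/FASTQ/TSV).

File parsing and formatting are delegated to Biopython's ``SeqIO``; this
module only wraps them around the package's light-weight read container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["ReadSet", "read_fasta", "write_fasta", "read_tsv", "write_tsv"]


@dataclass
class ReadSet:
    """A set of sequencing reads with per-base qualities.

    Invariants: one quality character per base in every record; identifiers
    are unique within the set.
    """

    ids: list[str] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)
    qualities: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, str, str]]:
        return iter(zip(self.ids, self.sequences, self.qualities))

    def validate(self) -> "ReadSet":
        if not (len(self.ids) == len(self.sequences) == len(self.qualities)):
            raise ValueError("ids, sequences and qualities differ in length")
        for s, q in zip(self.sequences, self.qualities):
            if len(s) != len(q):
                raise ValueError("sequence/quality length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("read identifiers are not unique")
        return self

    def subset(self, indices) -> "ReadSet":
        return ReadSet(
            [self.ids[i] for i in indices],
            [self.sequences[i] for i in indices],
            [self.qualities[i] for i in indices],
        )

    @classmethod
    def from_fastq(cls, path) -> "ReadSet":
        ids, seqs, quals = [], [], []
        for rec in SeqIO.parse(str(path), "fastq"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
            quals.append(
                "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            )
        return cls(ids, seqs, quals).validate()

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def to_fastq_string(self) -> str:
        return "".join(f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in self)


def read_fasta(path) -> dict[str, str]:
    """Return an ordered mapping of record id to uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str] | list[tuple[str, str]],
                descriptions: dict[str, str] | None = None) -> None:
    items = records.items() if isinstance(records, dict) else records
    recs = []
    for rid, seq in items:
        desc = (descriptions or {}).get(rid, "")
        recs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(recs, str(path), "fasta")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
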