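"""FASTA and table I/O for junction cohorts."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synthetic_data import SwitchReference

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_reference",
    "write_reference",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )


def read_reference(path: str | Path, role: str, name: str | None = None) -> SwitchReference:
    """Load the first record of a FASTA file as a donor/acceptor reference."""
    records = read_fasta(path)
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    rec_name, seq = records[0]
    return SwitchReference(name or rec_name, seq, role)


def write_reference(ref: SwitchReference, path: str | Path) -> None:
    write_fasta([(ref.name, ref.sequence)], path)
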