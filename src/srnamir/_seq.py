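"""Shared sequence helpers: alphabets, reverse complement, coordinates, FASTA I/O."""

from __future__ import annotations

from typing import Iterator

from Bio import SeqIO

DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: uppercase sequence}; duplicate ids are an error."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record id: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, records: Iterator[tuple[str, str]] | dict[str, str], width: int = 70) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# Coordinate conventions: external interfaces are 1-based inclusive (as in
# genome-browser style "chrom:start-end"); internal slices are 0-based half-open.

def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    if start1 < 1 or end1 < start1:
        raise ValueError(f"bad 1-based interval ({start1}, {end1})")
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"bad 0-based interval ({start0}, {end0})")
    return start0 + 1, end0
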