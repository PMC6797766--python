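"""Raw small-RNA read processing: FASTQ parsing, 3' adapter trimming, and
classification of every read into the five accounting categories
(low_quality, invalid_adapter, poly_a, short, clean) with the per-library
accounting table and insert-length distribution.

Classification rules (applied in strict precedence order):

1. low_quality   — mean Phred < 20, or more than 10% of bases with Q < 13;
2. invalid_adapter — no 3' adapter occurrence (full match anywhere, or a
   >= ``min_overlap`` nt adapter prefix at the read end); inserts longer than
   ``max_len`` also land here (no valid 3'-primer position in the retained
   window);
3. poly_a        — trimmed insert is >= 80% adenine;
4. short         — trimmed insert shorter than ``min_len`` (18 nt);
5. clean         — everything else; insert length within [min_len, max_len].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

CATEGORIES = ("low_quality", "invalid_adapter", "poly_a", "short", "clean")

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter


@dataclass
class QcParams:
    adapter3: str = DEFAULT_ADAPTER3
    min_overlap: int = 6
    min_len: int = 18
    max_len: int = 30
    mean_q_min: float = 20.0
    low_q: int = 13
    low_q_max_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.min_overlap < 6:
            raise ValueError("min_overlap must be >= 6")
        if len(self.adapter3) < 8:
            raise ValueError("adapter must be >= 8 nt")


@dataclass
class SmallRead:
    """One sequenced read with Phred qualities and (once classified) its
    category and trimmed insert."""

    id: str
    sequence: str
    quality: list[int]
    category: str | None = None
    insert: str | None = None


def parse_fastq(stream) -> list[SmallRead]:
    """Parse 4-line FASTQ records (Phred+33) into ``SmallRead`` objects.

    ``stream`` may be a path or an open text handle.  Malformed records raise
    ``ValueError`` naming the failing record index.
    """
    close = False
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        stream = open(stream)
        close = True
    reads: list[SmallRead] = []
    try:
        it = FastqGeneralIterator(stream)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {len(reads) + 1}: {exc}") from exc
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {len(reads) + 1}: sequence/quality length mismatch"
                )
            reads.append(
                SmallRead(
                    id=title.split()[0] if title else "",
                    sequence=seq.upper(),
                    quality=[ord(c) - 33 for c in qual],
                )
            )
    finally:
        if close:
            stream.close()
    return reads


def trim_adapter(sequence: str, adapter3: str, min_overlap: int = 6) -> str | None:
    """Insert before the leftmost 3' adapter occurrence, or None if no adapter.

    An occurrence is a full adapter match anywhere in the read, or a prefix of
    the adapter of length >= ``min_overlap`` at the very end of the read.
    """
    if min_overlap < 6:
        raise ValueError("min_overlap must be >= 6")
    pos = sequence.find(adapter3)
    if pos >= 0:
        return sequence[:pos]
    for k in range(min(len(adapter3), len(sequence)) - 1, min_overlap - 1, -1):
        if sequence.endswith(adapter3[:k]):
            return sequence[: len(sequence) - k]
    return None


def classify_read(read: SmallRead, params: QcParams) -> str:
    """Assign the read's accounting category (precedence order documented in
    the module docstring) and record the trimmed insert.  Pure in
    (sequence, quality, params)."""
    q = read.quality
    if q:
        mean_q = sum(q) / len(q)
        frac_low = sum(1 for v in q if v < params.low_q) / len(q)
        if mean_q < params.mean_q_min or frac_low > params.low_q_max_frac:
            read.category = "low_quality"
            return read.category
    insert = trim_adapter(read.sequence, params.adapter3, params.min_overlap)
    read.insert = insert
    if insert is None or len(insert) > params.max_len:
        read.category = "invalid_adapter"
        return read.category
    if insert and insert.count("A") / len(insert) >= 0.80:
        read.category = "poly_a"
        return read.category
    if len(insert) < params.min_len:
        read.category = "short"
        return read.category
    read.category = "clean"
    return read.category


def classify_library(reads: list[SmallRead], params: QcParams | None = None) -> list[SmallRead]:
    params = params or QcParams()
    for r in reads:
        classify_read(r, params)
    return reads


def accounting_from_counts(
    library: str,
    raw_total: int,
    low_quality: int,
    invalid_adapter: int,
    poly_a: int,
    short: int,
) -> dict:
    """One accounting row from per-class counts: clean reads are the raw total
    minus the four filtered classes, with the clean percentage at 2 decimals."""
    clean = raw_total - (low_quality + invalid_adapter + poly_a + short)
    if clean < 0:
        raise ValueError(f"filtered classes exceed raw total for {library}")
    if raw_total == 0:
        warnings.warn(f"library {library} has zero reads; clean percentage reported as 0.00")
        pct = 0.0
    else:
        pct = round(100.0 * clean / raw_total, 2)
    return {
        "library": library,
        "raw_total": raw_total,
        "low_quality": low_quality,
        "invalid_adapter": invalid_adapter,
        "poly_a": poly_a,
        "short": short,
        "clean": clean,
        "clean_pct": pct,
    }


def qc_accounting(libraries: dict[str, list[SmallRead]]) -> pd.DataFrame:
    """Accounting table (one row per library) from classified reads."""
    rows = []
    for name, reads in libraries.items():
        counts = {c: 0 for c in CATEGORIES}
        for r in reads:
            if r.category is None:
                raise ValueError(f"uncategorized read {r.id} in library {name}")
            counts[r.category] += 1
        rows.append(
            accounting_from_counts(
                name,
                len(reads),
                counts["low_quality"],
                counts["invalid_adapter"],
                counts["poly_a"],
                counts["short"],
            )
        )
        if rows[-1]["clean"] != counts["clean"]:  # conservation, by construction
            raise AssertionError("accounting conservation violated")
    return pd.DataFrame(rows).set_index("library")


def length_distribution(clean_reads, lo: int = 15, hi: int = 30) -> pd.Series:
    """Histogram of clean insert lengths over bins ``lo..hi`` plus an
    ``other`` overflow bucket for out-of-range lengths."""
    counts = {length: 0 for length in range(lo, hi + 1)}
    other = 0
    for r in clean_reads:
        ln = len(r.insert if isinstance(r, SmallRead) else r)
        if lo <= ln <= hi:
            counts[ln] += 1
        else:
            other += 1
    s = pd.Series(counts, name="count")
    s.index.name = "length"
    s.loc["other"] = other
    return s
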