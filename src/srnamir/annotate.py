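"""Unique-tag construction, ncRNA annotation and exact genome mapping.

Clean trimmed reads are collapsed to unique tags with per-library counts;
tags matching rRNA/tRNA/snRNA/snoRNA/scRNA decoy references are discarded
from miRNA analysis; the rest are exactly mapped to the genome on both
strands, feeding conserved and novel miRNA calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._seq import revcomp, to_one_based

NCRNA_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA")
MAX_LOCI_FOR_NOVEL = 20  # multi-mapping tags beyond this are repeat-like


@dataclass(frozen=True)
class Locus:
    """1-based inclusive genomic interval with strand (minus-strand hits are
    reported in plus-strand coordinates)."""

    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class UniqueTag:
    sequence: str
    counts: dict[str, int]
    annotation: str = "unannotated"
    loci: list[Locus] = field(default_factory=list)
    multimapped: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def collapse_unique(clean_inserts: dict[str, list[str]]) -> list[UniqueTag]:
    """Collapse per-library clean insert sequences into unique tags with a
    per-library count vector; total counts are conserved."""
    libraries = list(clean_inserts)
    tally: dict[str, dict[str, int]] = {}
    for lib in libraries:
        for seq in clean_inserts[lib]:
            row = tally.setdefault(seq, {l: 0 for l in libraries})
            row[lib] += 1
    return [UniqueTag(sequence=s, counts=c) for s, c in sorted(tally.items())]


class ExactIndex:
    """All-occurrence exact substring lookup over a FASTA-style reference set,
    on both strands.  Built for toy-scale references; the contract (every
    occurrence, plus- and minus-strand, 1-based output) is what matters."""

    def __init__(self, references: dict[str, str]):
        seen = set()
        for name in references:
            if name in seen:
                raise ValueError(f"duplicate reference id {name}")
            seen.add(name)
        if any(not s for s in references.values()):
            raise ValueError("empty reference sequence")
        self.references = {k: v.upper() for k, v in references.items()}

    def _find_all(self, text: str, pattern: str) -> list[int]:
        hits, start = [], 0
        while True:
            i = text.find(pattern, start)
            if i < 0:
                return hits
            hits.append(i)
            start = i + 1

    def query(self, pattern: str) -> list[Locus]:
        """Every occurrence of ``pattern`` or its reverse complement."""
        pattern = pattern.upper()
        rc = revcomp(pattern)
        out: list[Locus] = []
        for name, seq in self.references.items():
            for i in self._find_all(seq, pattern):
                s1, e1 = to_one_based(i, i + len(pattern))
                out.append(Locus(name, s1, e1, "+"))
            for i in self._find_all(seq, rc):
                s1, e1 = to_one_based(i, i + len(pattern))
                out.append(Locus(name, s1, e1, "-"))
        return out


def build_index(references: dict[str, str]) -> ExactIndex:
    return ExactIndex(references)


def build_ncrna_indexes(decoys: dict[str, str]) -> dict[str, ExactIndex]:
    """Split a decoy FASTA (record ids prefixed with their class, e.g.
    ``rRNA_1``) into one exact index per ncRNA class."""
    per_class: dict[str, dict[str, str]] = {c: {} for c in NCRNA_PRIORITY}
    for name, seq in decoys.items():
        cls = name.split("_")[0].split("|")[0]
        if cls not in per_class:
            raise ValueError(f"decoy record {name}: unknown ncRNA class {cls!r}")
        per_class[cls][name] = seq
    return {c: ExactIndex(refs) for c, refs in per_class.items() if refs}


def classify_ncrna(tag: UniqueTag, indexes: dict[str, ExactIndex]) -> str:
    """First matching class in the fixed priority rRNA > tRNA > snRNA >
    snoRNA > scRNA, or 'unannotated'.  Matching is exact substring occurrence
    in a decoy reference (either strand)."""
    for cls in NCRNA_PRIORITY:
        idx = indexes.get(cls)
        if idx is not None and idx.query(tag.sequence):
            tag.annotation = cls
            return cls
    tag.annotation = "unannotated"
    return tag.annotation


def map_read(tag: UniqueTag, genome_index: ExactIndex) -> list[Locus]:
    """Exact genome occurrences of the tag on both strands (mismatch-free, as
    required for novel-candidate eligibility).  Tags hitting more than
    ``MAX_LOCI_FOR_NOVEL`` loci are flagged as multi-mapped."""
    tag.loci = genome_index.query(tag.sequence)
    tag.multimapped = len(tag.loci) > MAX_LOCI_FOR_NOVEL
    return tag.loci


def tags_to_frame(tags: list[UniqueTag], libraries: list[str]) -> pd.DataFrame:
    rows = []
    for t in tags:
        row = {"sequence": t.sequence, "annotation": t.annotation, "n_loci": len(t.loci)}
        row.update({lib: t.counts.get(lib, 0) for lib in libraries})
        rows.append(row)
    return pd.DataFrame(rows)


def loci_to_gff3(tags: list[UniqueTag]) -> str:
    """GFF3 (type sRNA_tag) of every mapped locus of every tag."""
    lines = ["##gff-version 3"]
    for n, t in enumerate(tags, 1):
        for loc in t.loci:
            attrs = f"ID=tag{n:05d};seq={t.sequence};annotation={t.annotation}"
            lines.append(
                "\t".join(
                    [loc.chrom, "srnamir", "sRNA_tag", str(loc.start), str(loc.end),
                     ".", loc.strand, ".", attrs]
                )
            )
    return "\n".join(lines) + "\n"
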