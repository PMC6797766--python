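"""Conserved miRNA calling: ungapped best-hit matching of sequenced tags
against a known mature-miRNA reference set with at most three mismatches,
the minimum read-count filter, MIR-family aggregation and abundance ranking.

The mismatch model overlays the tag on the reference at every ungapped offset
leaving at most 2 nt of overhang per side; the score is the Hamming distance
within the overlap plus all overhang bases, so isomiR-style length differences
count against the 3-mismatch budget.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

MAX_OVERHANG = 2
_FAMILY_RE = re.compile(r"^[a-z]{3,4}-mir(?P<num>\d+)", re.IGNORECASE)


@dataclass
class ConservedCall:
    sequence: str
    reference: str
    mismatches: int
    counts: dict[str, int]
    family: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _overlay_score(tag: str, ref: str, offset: int) -> int | None:
    """Score of the ungapped overlay placing ``ref`` start at ``offset``
    relative to the tag start; None if overhangs exceed the limit or there is
    no overlap.  Score = mismatches within overlap + overhang bases."""
    left = abs(offset)
    right = abs(len(tag) - (offset + len(ref)))
    if left > MAX_OVERHANG or right > MAX_OVERHANG:
        return None
    lo = max(0, offset)
    hi = min(len(tag), offset + len(ref))
    if hi <= lo:
        return None
    mm = sum(1 for i in range(lo, hi) if tag[i] != ref[i - offset])
    return mm + left + right


def match_conserved(
    tag_sequence: str,
    reference: dict[str, str],
    max_mismatch: int = 3,
    counts: dict[str, int] | None = None,
) -> ConservedCall | None:
    """Best conserved-miRNA hit for a tag, or None if every overlay scores
    above ``max_mismatch``.  Ties are broken by fewest overhang bases, then
    lexicographic reference name."""
    tag = tag_sequence.upper().replace("U", "T")
    best: tuple[int, int, str] | None = None
    for name in sorted(reference):
        ref = reference[name].upper().replace("U", "T")
        for offset in range(-MAX_OVERHANG, len(tag) - len(ref) + MAX_OVERHANG + 1):
            score = _overlay_score(tag, ref, offset)
            if score is None:
                continue
            over = abs(offset) + abs(len(tag) - (offset + len(ref)))
            key = (score, over, name)
            if best is None or key < best:
                best = key
    if best is None or best[0] > max_mismatch:
        return None
    call = ConservedCall(
        sequence=tag_sequence,
        reference=best[2],
        mismatches=best[0],
        counts=dict(counts or {}),
    )
    call.family = family_assign(call.reference)
    return call


def filter_min_count(calls: list[ConservedCall], min_total: int = 10) -> list[ConservedCall]:
    """Retain calls whose summed count across all libraries reaches
    ``min_total`` (inclusive boundary)."""
    return [c for c in calls if c.total >= min_total]


def family_assign(reference_name: str) -> str:
    """MIR family from a mature-miRNA name: species prefix and letter/arm
    suffixes stripped, e.g. bra-miR156a-3p -> MIR156.  Unparseable names map
    to UNKNOWN with a warning."""
    m = _FAMILY_RE.match(reference_name.strip())
    if not m:
        warnings.warn(f"cannot parse miRNA family from name {reference_name!r}")
        return "UNKNOWN"
    return f"MIR{m.group('num')}"


def family_table(calls: list[ConservedCall]) -> pd.DataFrame:
    """Per-family tally: member count and summed reads, by descending reads."""
    rows: dict[str, dict] = {}
    for c in calls:
        row = rows.setdefault(c.family, {"family": c.family, "members": 0, "reads": 0})
        row["members"] += 1
        row["reads"] += c.total
    df = pd.DataFrame(rows.values(), columns=["family", "members", "reads"])
    return df.sort_values(["reads", "family"], ascending=[False, True]).reset_index(drop=True)


def rank_abundance(
    calls: list[ConservedCall], library_totals: dict[str, int], top_n: int = 15
) -> pd.DataFrame:
    """Top-N calls by summed reads-per-million across libraries; ties broken
    lexicographically by reference name."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    rows = []
    for c in calls:
        rpm = sum(
            1e6 * c.counts.get(lib, 0) / tot for lib, tot in library_totals.items() if tot > 0
        )
        rows.append({"reference": c.reference, "family": c.family, "rpm_total": rpm})
    df = pd.DataFrame(rows, columns=["reference", "family", "rpm_total"])
    df = df.sort_values(["rpm_total", "reference"], ascending=[False, True])
    return df.head(top_n).reset_index(drop=True)


def calls_to_frame(calls: list[ConservedCall], libraries: list[str]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "reference": c.reference,
            "sequence": c.sequence,
            "mismatches": c.mismatches,
            "family": c.family,
        }
        row.update({lib: c.counts.get(lib, 0) for lib in libraries})
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["reference", "sequence", "mismatches", "family", *libraries]
    )
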