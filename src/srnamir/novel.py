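"""Novel miRNA prediction from exactly-mapped, unannotated tags.

For each candidate locus, precursor windows are excised around the mature
tag, folded, and screened with hairpin-duplex criteria: the mature and its
star partner must form a duplex on opposite stem arms with 2-nt 3' overhangs,
fewer than 3 mismatched mature bases, at most one asymmetric bulge, a folded
MFEI of at least the threshold (default 0.8), and the star sequence must be
present among the sequenced tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import fold as fold_mod
from ._seq import revcomp, to_dna, to_zero_based
from .annotate import Locus, UniqueTag

MFEI_THRESHOLD = 0.8
FLANK = 150
MAX_PRECURSOR = 320
END_PAD = 20
STAR_SLACK = 2  # nt of 3'-end slack when matching star reads
OVERHANG = 2  # canonical Dicer 2-nt 3' overhang


@dataclass(frozen=True)
class PrecursorWindow:
    """A genomic window (1-based inclusive, strand-oriented sequence) holding
    the mature tag at ``mature_offset`` (0-based within ``sequence``)."""

    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    mature_offset: int
    mature_len: int


@dataclass(frozen=True)
class StarPlacement:
    start: int  # 0-based offset within the precursor
    length: int
    arm: str  # arm holding the *mature* ('5p' or '3p')


@dataclass
class NovelCandidate:
    locus: Locus
    window: PrecursorWindow
    fold: fold_mod.HairpinFold
    mature_offset: int
    mature_len: int
    star: StarPlacement | None
    duplex_mismatches: int | None = None
    asymmetric_bulges: int | None = None
    overhang3_mature: int | None = None
    overhang3_star: int | None = None
    star_read_count: int = 0
    verdict: str = "fail"
    failed_rules: list[str] = field(default_factory=list)

    @property
    def mature_seq(self) -> str:
        return self.window.sequence[self.mature_offset : self.mature_offset + self.mature_len]

    @property
    def star_seq(self) -> str | None:
        if self.star is None:
            return None
        return self.window.sequence[self.star.start : self.star.start + self.star.length]


def extract_precursor_candidates(
    locus: Locus,
    genome: dict[str, str],
    flank: int = FLANK,
    max_precursor: int = MAX_PRECURSOR,
    end_pad: int = END_PAD,
) -> list[PrecursorWindow]:
    """Candidate precursor windows around a mapped mature locus: one centred
    window plus two asymmetric variants (mature near the 5' end, mature near
    the 3' end), each capped at ``max_precursor`` nt and clipped at chromosome
    ends.  Minus-strand windows are reverse-complemented so the returned
    sequence always reads 5'->3' with the mature verbatim."""
    if locus.chrom not in genome:
        raise ValueError(f"locus chromosome {locus.chrom} not in genome")
    chrom_seq = genome[locus.chrom]
    s0, e0 = to_zero_based(locus.start, locus.end)
    if e0 > len(chrom_seq):
        raise ValueError(f"locus {locus} outside chromosome {locus.chrom}")
    mlen = e0 - s0
    half = min(flank, (max_precursor - mlen) // 2)
    big = max_precursor - mlen - end_pad
    shapes = [(half, half), (end_pad, big), (big, end_pad)]
    windows: list[PrecursorWindow] = []
    seen: set[tuple[int, int]] = set()
    for up, down in shapes:
        if locus.strand == "+":
            w0 = max(0, s0 - up)
            w1 = min(len(chrom_seq), e0 + down)
        else:  # 5' of the tag is the genomic right side
            w0 = max(0, s0 - down)
            w1 = min(len(chrom_seq), e0 + up)
        if (w0, w1) in seen:
            continue
        seen.add((w0, w1))
        seq = chrom_seq[w0:w1]
        if locus.strand == "+":
            offset = s0 - w0
        else:
            seq = revcomp(seq)
            offset = w1 - e0
        windows.append(
            PrecursorWindow(
                chrom=locus.chrom,
                start=w0 + 1,
                end=w1,
                strand=locus.strand,
                sequence=seq,
                mature_offset=offset,
                mature_len=mlen,
            )
        )
    return windows


def find_star(
    hairpin: fold_mod.HairpinFold, mature_offset: int, mature_len: int
) -> StarPlacement | None:
    """Star placement for a mature arm: the pairing-partner interval of the
    mature, shifted 2 nt in the 3' coordinate direction so both duplex ends
    carry the canonical 2-nt 3' overhang (in precursor coordinates both
    strands' 3' ends point the same way, so the shift is +2 on either arm).
    None when fewer than 60% of mature bases pair consistently toward one
    side (mature spanning the loop or unpaired)."""
    n = len(hairpin.sequence)
    partner = hairpin.partner_map()
    m_lo, m_hi = mature_offset, mature_offset + mature_len - 1
    down = [partner[i] for i in range(m_lo, m_hi + 1) if i in partner and partner[i] > m_hi]
    up = [partner[i] for i in range(m_lo, m_hi + 1) if i in partner and partner[i] < m_lo]
    need = 0.6 * mature_len
    if len(down) >= need and len(down) > len(up):
        arm, partners = "5p", down
    elif len(up) >= need and len(up) > len(down):
        arm, partners = "3p", up
    else:
        return None
    p_lo, p_hi = min(partners), max(partners)
    s_lo, s_hi = p_lo + OVERHANG, p_hi + OVERHANG
    if s_lo < 0 or s_hi >= n:
        return None
    return StarPlacement(start=s_lo, length=s_hi - s_lo + 1, arm=arm)


def duplex_check(
    hairpin: fold_mod.HairpinFold,
    mature_offset: int,
    mature_len: int,
    star: StarPlacement,
) -> tuple[int, int, tuple[int, int], bool]:
    """Duplex diagnostics for a mature/star placement.

    Returns (mismatches, asymmetric_bulge_runs, (overhang3_mature,
    overhang3_star), pass).  The duplex region of each strand excludes its
    own 2-nt 3' overhang; a mismatch is a duplex mature base unpaired or
    paired outside the star interval; an asymmetric bulge is a maximal
    unpaired run on one duplex strand with zero opposite; pass requires
    mismatches < 3, at most one bulge run and a >= 1 nt 3' overhang on both
    strands (3'-terminal bases not pairing into the partner).
    """
    partner = hairpin.partner_map()
    s_lo, s_hi = star.start, star.start + star.length - 1
    m_lo, m_hi = mature_offset, mature_offset + mature_len - 1
    in_star = lambda p: s_lo <= p <= s_hi
    in_mature = lambda p: m_lo <= p <= m_hi
    duplex_m = range(m_lo, m_hi + 1 - OVERHANG)  # exclude the mature's own 3' overhang
    paired = [(m, partner[m]) for m in duplex_m if m in partner and in_star(partner[m])]
    mismatches = len(duplex_m) - len(paired)

    bulges = 0
    for (m1, p1), (m2, p2) in zip(paired, paired[1:]):
        gap_m = m2 - m1 - 1
        gap_s = abs(p2 - p1) - 1
        if (gap_m == 0) != (gap_s == 0):
            bulges += 1

    over_m = 0
    for m in range(m_hi, m_lo - 1, -1):
        if m in partner and in_star(partner[m]):
            break
        over_m += 1
    over_s = 0
    for p in range(s_hi, s_lo - 1, -1):
        if p in partner and in_mature(partner[p]):
            break
        over_s += 1
    ok = mismatches < 3 and bulges <= 1 and over_m >= 1 and over_s >= 1
    return mismatches, bulges, (over_m, over_s), ok


def _star_evidence(window: PrecursorWindow, star: StarPlacement, tags: dict[str, int]) -> int:
    """Summed read count of sequenced tags matching the star sequence, with
    up to ``STAR_SLACK`` nt of 3'-end slack (shared 5' end)."""
    seq = window.sequence
    lo = star.start
    total = 0
    for length in range(star.length - STAR_SLACK, star.length + STAR_SLACK + 1):
        if length < 1 or lo + length > len(seq):
            continue
        total += tags.get(to_dna(seq[lo : lo + length]), 0)
    return total


def assess_windows(
    locus: Locus,
    windows: list[PrecursorWindow],
    tag_counts: dict[str, int],
    mfei_threshold: float = MFEI_THRESHOLD,
) -> list[NovelCandidate]:
    """Fold and screen every window, returning one diagnosed candidate per
    window with its verdict and the list of failed rules."""
    out: list[NovelCandidate] = []
    for w in windows:
        hp = fold_mod.fold_mfe(w.sequence)
        star = find_star(hp, w.mature_offset, w.mature_len)
        cand = NovelCandidate(
            locus=locus,
            window=w,
            fold=hp,
            mature_offset=w.mature_offset,
            mature_len=w.mature_len,
            star=star,
        )
        failed: list[str] = []
        if star is None:
            failed.append("no_star_arm")
        else:
            mm, bulges, (om, os_), _ = duplex_check(hp, w.mature_offset, w.mature_len, star)
            cand.duplex_mismatches = mm
            cand.asymmetric_bulges = bulges
            cand.overhang3_mature = om
            cand.overhang3_star = os_
            if mm >= 3:
                failed.append("mismatches")
            if bulges > 1:
                failed.append("asymmetric_bulges")
            if om < 1 or os_ < 1:
                failed.append("overhang")
            cand.star_read_count = _star_evidence(w, star, tag_counts)
            if cand.star_read_count < 1:
                failed.append("star_reads")
        if not (hp.mfei >= mfei_threshold):
            failed.append("mfei")
        cand.failed_rules = failed
        cand.verdict = "pass" if not failed else "fail"
        out.append(cand)
    return out


def evaluate_candidate(
    locus: Locus,
    windows: list[PrecursorWindow],
    tag_counts: dict[str, int],
    mfei_threshold: float = MFEI_THRESHOLD,
) -> NovelCandidate | None:
    """Best passing candidate across the windows of a locus (lowest folded
    MFE), or None when every window fails the criteria."""
    passing = [c for c in assess_windows(locus, windows, tag_counts, mfei_threshold)
               if c.verdict == "pass"]
    if not passing:
        return None
    return min(passing, key=lambda c: (c.fold.mfe, c.window.start))


def call_novel(
    tags: list[UniqueTag],
    genome: dict[str, str],
    mfei_threshold: float = MFEI_THRESHOLD,
    flank: int = FLANK,
) -> list[NovelCandidate]:
    """Run the full novel-miRNA screen over unannotated, exactly-mapped,
    non-multimapped tags.  Star-read evidence is drawn from the same tag set.

    Each precursor is reported once: tags are screened in descending
    abundance, and a tag whose locus falls inside an already-accepted
    precursor window (the star product of a called miRNA, typically) is
    folded into that call rather than reported again."""
    counts = {t.sequence: t.total for t in tags}
    results: list[NovelCandidate] = []
    accepted: list[tuple[str, int, int]] = []
    for tag in sorted(tags, key=lambda t: (-t.total, t.sequence)):
        if tag.annotation != "unannotated" or tag.multimapped or not tag.loci:
            continue
        if any(
            loc.chrom == c and loc.start <= e and loc.end >= s
            for loc in tag.loci
            for c, s, e in accepted
        ):
            continue
        best: NovelCandidate | None = None
        for locus in tag.loci:
            windows = extract_precursor_candidates(locus, genome, flank=flank)
            cand = evaluate_candidate(locus, windows, counts, mfei_threshold)
            if cand is not None and (best is None or cand.fold.mfe < best.fold.mfe):
                best = cand
        if best is not None:
            best.tag_counts = dict(tag.counts)  # type: ignore[attr-defined]
            results.append(best)
            accepted.append((best.window.chrom, best.window.start, best.window.end))
    return results


def report_novel(candidates: list[NovelCandidate]) -> pd.DataFrame:
    """Novel-miRNA report: candidates named novel-mirNNN in genomic order,
    with location (1-based), mature length, strand and mature sequence."""
    ordered = sorted(candidates, key=lambda c: (c.locus.chrom, c.locus.start))
    rows = []
    for i, c in enumerate(ordered, 1):
        mature = to_dna(c.mature_seq)
        rows.append(
            {
                "name": f"novel-mir{i:03d}",
                "location": f"{c.locus.chrom}:{c.locus.start}-{c.locus.end}",
                "length": len(mature),
                "strand": c.locus.strand,
                "mature_sequence": mature,
            }
        )
    return pd.DataFrame(rows, columns=["name", "location", "length", "strand", "mature_sequence"])


def precursors_to_gff3(candidates: list[NovelCandidate]) -> str:
    lines = ["##gff-version 3"]
    ordered = sorted(candidates, key=lambda c: (c.locus.chrom, c.locus.start))
    for i, c in enumerate(ordered, 1):
        name = f"novel-mir{i:03d}"
        w = c.window
        lines.append("\t".join([
            w.chrom, "srnamir", "miRNA_primary_transcript", str(w.start), str(w.end),
            ".", w.strand, ".", f"ID={name}",
        ]))
        for kind, off, ln in [
            ("miRNA", c.mature_offset, c.mature_len),
            ("miRNA_star", c.star.start if c.star else 0, c.star.length if c.star else 0),
        ]:
            if ln == 0:
                continue
            if w.strand == "+":
                s = w.start + off
                e = s + ln - 1
            else:
                e = w.end - off
                s = e - ln + 1
            lines.append("\t".join([
                w.chrom, "srnamir", kind, str(s), str(e), ".", w.strand, ".",
                f"ID={name}.{kind};Parent={name}",
            ]))
    return "\n".join(lines) + "\n"


def structures_text(candidates: list[NovelCandidate]) -> str:
    """Dot-bracket record per candidate (FASTA-style header, sequence,
    structure and energy line)."""
    ordered = sorted(candidates, key=lambda c: (c.locus.chrom, c.locus.start))
    chunks = []
    for i, c in enumerate(ordered, 1):
        chunks.append(
            f">novel-mir{i:03d} {c.locus.chrom}:{c.locus.start}-{c.locus.end}({c.locus.strand})"
            f" mfe={c.fold.mfe:.1f} mfei={c.fold.mfei:.3f}\n"
            f"{c.fold.sequence}\n{c.fold.dot_bracket}\n"
        )
    return "".join(chunks)
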