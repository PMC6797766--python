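"""Synthetic small-RNA study generator with recorded ground truth.

Emulates the full input bundle of a four-library heat-stress time course
(0 h control, 1 h, 6 h, 12 h): a multi-chromosome genome with planted
stem-loop miRNA precursors, a conserved mature-miRNA reference (41 matures in
19 MIR families), ncRNA decoy references, per-library count vectors with
planted log2 fold changes, FASTQ reads with 3' adapter and per-class
contamination, and a Ct table consistent with the planted fold changes.
Every random draw flows from one integer seed, so identical seeds give
byte-identical outputs.

Planted hairpins are built arm-by-arm: a GC-enriched (~55%) lower stem, the
mature sequence, an upper stem and loop, then the 3' arm as the (partially
mismatched) reverse complement.  The star sequence is derived from the
designed pairing with the canonical 2-nt 3' overhang shift, so each hairpin
is constructed to pass or fail the duplex criteria exactly as parameterized
and the truth records which.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp
from .readqc import DEFAULT_ADAPTER3, trim_adapter

LIBRARIES = ("0h", "1h", "6h", "12h")
TIMEPOINTS = ("1h", "6h", "12h")
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "scRNA")

# Per-library contamination fractions of the raw total, matching the
# published accounting proportions of a real four-library sRNA run
# (~7-8% non-clean overall).
TABLE1_RATES: dict[str, dict[str, float]] = {
    "0h": {"low_quality": 476790 / 28194816, "invalid_adapter": 395757 / 28194816,
           "poly_a": 775 / 28194816, "short": 1027684 / 28194816},
    "1h": {"low_quality": 619057 / 29746062, "invalid_adapter": 416205 / 29746062,
           "poly_a": 684 / 29746062, "short": 983780 / 29746062},
    "6h": {"low_quality": 568450 / 28002965, "invalid_adapter": 423553 / 28002965,
           "poly_a": 746 / 28002965, "short": 1126302 / 28002965},
    "12h": {"low_quality": 486853 / 29049979, "invalid_adapter": 442446 / 29049979,
            "poly_a": 726 / 29049979, "short": 1475483 / 29049979},
}

MFEI_BAND = (0.8, 2.2)  # MFEI range typical of plant miRNA precursors

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# 19 MIR families; 41 mature members spread over them
_FAMILIES = (156, 158, 159, 160, 162, 164, 166, 167, 168, 169,
             171, 172, 390, 395, 396, 398, 403, 1885, 5725)
_MEMBERS_PER_FAMILY = (3, 2, 3, 2, 2, 2, 2, 2, 3, 2, 3, 2, 2, 2, 2, 2, 2, 2, 1)


@dataclass
class PlantedHairpin:
    name: str
    chrom: str
    start: int  # 1-based inclusive genomic span of the precursor
    end: int
    strand: str
    mature_arm: str
    mature_seq: str  # DNA, 5'->3' on the hairpin strand
    star_seq: str
    loop_len: int
    precursor_seq: str
    mature_offset: int  # 0-based within precursor_seq
    star_offset: int
    planted_mismatches: int
    planted_bulges: int
    has_star_reads: bool
    expected_pass: bool
    designed_pairs: list[tuple[int, int]] = field(repr=False, default_factory=list)


@dataclass
class TruthSet:
    genome_id: str
    genome: dict[str, str]
    hairpins: list[PlantedHairpin]
    mature_reference: dict[str, str]
    ncrna_decoys: dict[str, str]
    expression: pd.DataFrame  # index id; columns kind, sequence, mean, lfc_<tp>
    contamination_rates: dict[str, dict[str, float]]
    seed: int
    libraries: tuple[str, ...] = LIBRARIES
    read_class_truth: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def true_log2fc(self) -> pd.DataFrame:
        cols = {f"lfc_{tp}": tp for tp in TIMEPOINTS}
        return self.expression[list(cols)].rename(columns=cols)


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _rand_insert(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """Random insert that cannot be mistaken for a poly-A tag."""
    while True:
        s = _rand_seq(rng, n, gc)
        if s.count("A") / n < 0.8:
            return s


@dataclass
class HairpinDesign:
    precursor: str
    mature_offset: int
    mature_len: int
    star_offset: int
    star_len: int
    loop_len: int
    designed_pairs: list[tuple[int, int]]
    mismatches: int
    bulges: int

    @property
    def mature_seq(self) -> str:
        return self.precursor[self.mature_offset : self.mature_offset + self.mature_len]

    @property
    def star_seq(self) -> str:
        return self.precursor[self.star_offset : self.star_offset + self.star_len]


def plant_hairpin(
    seed_or_rng,
    mature_len: int = 21,
    loop_len: int = 8,
    stem_mismatches: int = 0,
    bulges: int = 0,
    bulge_len: int = 1,
    span: int = 160,
    stem_gc: float = 0.55,
    lower_loop_rate: float = 0.18,
    upper_len: int = 10,
) -> HairpinDesign:
    """Construct one stem-loop precursor with the mature on the 5' arm and
    ``stem_mismatches`` / ``bulges`` planted inside the mature/star duplex.

    The designed pairing gives the mature a fully complementary partner
    except at the planted positions; the star is the partner interval shifted
    2 nt 3'-ward (Dicer geometry).  The 3 terminal bases of the mature and
    the 2 lower-stem bases flanking it always pair, so the duplex register is
    stable under refolding.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    if not 18 <= mature_len <= 26:
        raise ValueError("mature_len must be in [18, 26]")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    arm_len = (span - loop_len) // 2
    lower_len = arm_len - mature_len - upper_len
    if lower_len < 4:
        raise ValueError(f"span {span} too small for mature_len {mature_len}")
    interior = list(range(lower_len + 3, lower_len + mature_len - 3))
    if stem_mismatches + bulges > len(interior) // 2:
        raise ValueError("too many planted mismatches/bulges for the mature length")

    arm5 = _rand_seq(rng, lower_len, stem_gc) + _rand_seq(rng, mature_len, stem_gc) \
        + _rand_seq(rng, upper_len, stem_gc)
    loop = _rand_seq(rng, loop_len, 0.3)

    mm_pos = set(rng.choice(interior, size=stem_mismatches, replace=False).tolist())
    remaining = [p for p in interior if p not in mm_pos and p - 1 not in mm_pos and p + 1 not in mm_pos]
    bulge_after = set(rng.choice(remaining, size=bulges, replace=False).tolist()) if bulges else set()
    # G.U wobble pairs inside the duplex: still paired (no mismatch cost) but
    # they break exact reverse-complementarity, so the mature maps to a single
    # genomic locus, as real Dicer duplexes do
    wobble_ok = [p for p in interior if p not in mm_pos and arm5[p] in "GT"]
    if not wobble_ok:
        raise RuntimeError("mature interior has no G/T position for a wobble pair")
    wobble_pos = set(rng.choice(wobble_ok, size=min(2, len(wobble_ok)), replace=False).tolist())
    # lower-stem interior loops keep the MFEI of long precursors realistic
    protected = set(range(lower_len - 2, lower_len))
    loop_pos = {p for p in range(lower_len)
                if p not in protected and rng.random() < lower_loop_rate}

    n5 = len(arm5)
    arm3_chars: list[str] = []
    partner_of: dict[int, int] = {}  # arm5 index -> index within arm3 list
    for k in range(n5 - 1, -1, -1):
        if k in mm_pos or k in loop_pos:
            arm3_chars.append(arm5[k])  # same base never pairs with itself
        elif k in wobble_pos:
            partner_of[k] = len(arm3_chars)
            arm3_chars.append("T" if arm5[k] == "G" else "G")
        else:
            partner_of[k] = len(arm3_chars)
            arm3_chars.append(_COMP[arm5[k]])
        if k in bulge_after:  # extra unpaired bases on the star strand
            for _ in range(bulge_len):
                arm3_chars.append(arm5[k])
    arm3 = "".join(arm3_chars)

    precursor = arm5 + loop + arm3
    off3 = n5 + loop_len
    pairs = [(k, off3 + idx) for k, idx in partner_of.items()]
    pairs.sort()

    m_lo = lower_len
    m_hi = lower_len + mature_len - 1
    partners = [off3 + partner_of[k] for k in range(m_lo, m_hi + 1) if k in partner_of]
    star_lo = min(partners) + 2
    star_hi = max(partners) + 2
    return HairpinDesign(
        precursor=precursor,
        mature_offset=m_lo,
        mature_len=mature_len,
        star_offset=star_lo,
        star_len=star_hi - star_lo + 1,
        loop_len=loop_len,
        designed_pairs=pairs,
        mismatches=stem_mismatches,
        bulges=bulges,
    )


def _design_with_verdict(rng: np.random.Generator, spec: dict, max_tries: int = 30) -> HairpinDesign:
    """Draw hairpin designs until the refolded structure reproduces the
    intended duplex verdict (pass iff planted mismatches < 3 and bulges <= 1).

    Refolding can occasionally absorb a planted defect into an alternative
    pairing (or add one), so the construction contract — the truth records
    exactly whether each hairpin satisfies the duplex criteria — is enforced
    by verification at build time.  For structurally passing designs the
    refolded star placement must also coincide with the designed one, so the
    emitted star reads are the evidence the screen will look for.
    """
    from . import fold as fold_mod
    from . import novel as novel_mod

    want_pass = spec["mismatches"] < 3 and spec["bulges"] <= 1
    for _ in range(max_tries):
        design = plant_hairpin(
            rng,
            mature_len=spec["mature_len"],
            span=spec["span"],
            stem_mismatches=spec["mismatches"],
            bulges=spec["bulges"],
            bulge_len=spec.get("bulge_len", 1),
        )
        folded = fold_mod.fold_mfe(design.precursor)
        star = novel_mod.find_star(folded, design.mature_offset, design.mature_len)
        if star is None:
            ok = False
        else:
            _, _, _, ok = novel_mod.duplex_check(
                folded, design.mature_offset, design.mature_len, star
            )
        if ok != want_pass:
            continue
        if want_pass and (star.start != design.star_offset or star.length != design.star_len):
            continue
        if not MFEI_BAND[0] <= folded.mfei <= MFEI_BAND[1]:
            continue  # keep precursors inside the band typical of plant pre-miRNAs
        return design
    raise RuntimeError(f"could not realize hairpin spec {spec['name']} in {max_tries} draws")


def default_hairpin_specs() -> list[dict]:
    """Ten planted precursors: six constructed to pass the duplex screen
    (with benign 0-2 mismatch / 0-1 bulge variation) and four constructed to
    fail for a specific rule."""
    return [
        dict(name="hp01", mature_len=21, span=150, mismatches=0, bulges=0, star_reads=True, expect="pass"),
        dict(name="hp02", mature_len=22, span=170, mismatches=1, bulges=0, star_reads=True, expect="pass"),
        dict(name="hp03", mature_len=24, span=200, mismatches=2, bulges=0, star_reads=True, expect="pass"),
        dict(name="hp04", mature_len=20, span=140, mismatches=0, bulges=1, star_reads=True, expect="pass"),
        dict(name="hp05", mature_len=23, span=240, mismatches=1, bulges=1, star_reads=True, expect="pass"),
        dict(name="hp06", mature_len=25, span=220, mismatches=0, bulges=1, star_reads=True, expect="pass"),
        dict(name="hp07", mature_len=21, span=160, mismatches=3, bulges=0, star_reads=True, expect="fail"),
        dict(name="hp08", mature_len=22, span=190, mismatches=4, bulges=0, star_reads=True, expect="fail"),
        dict(name="hp09", mature_len=21, span=170, mismatches=0, bulges=2, bulge_len=3, star_reads=True, expect="fail"),
        dict(name="hp10", mature_len=22, span=160, mismatches=0, bulges=0, star_reads=False, expect="fail"),
    ]


def _make_reference(rng: np.random.Generator) -> dict[str, str]:
    """41 conserved mature sequences across 19 MIR families; family members
    are 1-2 substitutions apart, families are independent random draws."""
    letters = "abc"
    ref: dict[str, str] = {}
    for fam, k in zip(_FAMILIES, _MEMBERS_PER_FAMILY):
        base = _rand_insert(rng, int(rng.integers(20, 25)))
        for i in range(k):
            seq = list(base)
            if i > 0:
                for p in rng.choice(len(seq), size=int(rng.integers(1, 3)), replace=False):
                    seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p]]))
            if k == 1:
                name = f"bra-miR{fam}"
            else:
                name = f"bra-miR{fam}{letters[i // 2]}{'-5p' if i % 2 == 0 else '-3p'}"
            ref[name] = "".join(seq)
    return ref


def _make_decoys(rng: np.random.Generator) -> dict[str, str]:
    return {
        f"{cls}_{i}": _rand_seq(rng, int(rng.integers(100, 300)))
        for cls in NCRNA_CLASSES
        for i in (1, 2)
    }


def _place_hairpins(
    rng: np.random.Generator,
    chroms: dict[str, np.ndarray],
    designs: list[tuple[dict, HairpinDesign]],
    margin: int = 400,
) -> list[PlantedHairpin]:
    names = list(chroms)
    cursors = {c: margin for c in names}
    out = []
    for i, (spec, design) in enumerate(designs):
        chrom = names[i % len(names)]
        start0 = cursors[chrom] + int(rng.integers(0, 200))
        end0 = start0 + len(design.precursor)
        if end0 > len(chroms[chrom]) - margin:
            raise ValueError(
                f"hairpin {spec['name']} does not fit: chromosome {chrom} capacity "
                f"exhausted at offset {start0} (len {len(chroms[chrom])}, margin {margin})"
            )
        cursors[chrom] = end0 + margin
        strand = "+" if rng.random() < 0.5 else "-"
        segment = design.precursor if strand == "+" else revcomp(design.precursor)
        chroms[chrom][start0:end0] = np.frombuffer(segment.encode(), dtype="S1")
        out.append(
            PlantedHairpin(
                name=spec["name"],
                chrom=chrom,
                start=start0 + 1,
                end=end0,
                strand=strand,
                mature_arm="5p",
                mature_seq=design.mature_seq,
                star_seq=design.star_seq,
                loop_len=design.loop_len,
                precursor_seq=design.precursor,
                mature_offset=design.mature_offset,
                star_offset=design.star_offset,
                planted_mismatches=design.mismatches,
                planted_bulges=design.bulges,
                has_star_reads=spec["star_reads"],
                expected_pass=spec["expect"] == "pass",
                designed_pairs=design.designed_pairs,
            )
        )
    return out


def _count_occurrences(genome: dict[str, str], pattern: str) -> int:
    total = 0
    for pat in (pattern, revcomp(pattern)):
        for seq in genome.values():
            start = 0
            while True:
                i = seq.find(pat, start)
                if i < 0:
                    break
                total += 1
                start = i + 1
    return total


def make_genome(
    seed: int,
    n_chrom: int = 2,
    chrom_len: int = 50_000,
    hairpin_specs: list[dict] | None = None,
) -> tuple[dict[str, str], TruthSet]:
    """Generate the genome and the complete truth set (reference, decoys,
    expression means and planted fold changes).  Deterministic in ``seed``."""
    specs = hairpin_specs if hairpin_specs is not None else default_hairpin_specs()
    max_span = max(s["span"] for s in specs) if specs else 320
    if chrom_len < 2 * max_span:
        raise ValueError(f"chrom_len {chrom_len} < twice the max hairpin span {max_span}")
    rng = np.random.default_rng(seed)
    reference = _make_reference(rng)
    decoys = _make_decoys(rng)
    designs = [(spec, _design_with_verdict(rng, spec)) for spec in specs]
    chroms = {
        f"A{c + 1:02d}": np.frombuffer(_rand_seq(rng, chrom_len).encode(), dtype="S1").copy()
        for c in range(n_chrom)
    }
    hairpins = _place_hairpins(rng, chroms, designs)
    genome = {name: arr.tobytes().decode() for name, arr in chroms.items()}

    for hp in hairpins:
        if _count_occurrences(genome, hp.mature_seq) != 1:
            raise RuntimeError(f"planted mature of {hp.name} is not unique in the genome")

    expression = _make_expression(rng, genome, hairpins, reference, decoys)
    truth = TruthSet(
        genome_id=f"sim-genome-seed{seed}",
        genome=genome,
        hairpins=hairpins,
        mature_reference=reference,
        ncrna_decoys=decoys,
        expression=expression,
        contamination_rates={lib: dict(TABLE1_RATES[lib]) for lib in LIBRARIES},
        seed=seed,
    )
    return genome, truth


def _make_expression(
    rng: np.random.Generator,
    genome: dict[str, str],
    hairpins: list[PlantedHairpin],
    reference: dict[str, str],
    decoys: dict[str, str],
) -> pd.DataFrame:
    rows = []
    ref_names = sorted(reference)
    # planted DE among conserved: 5 up, 5 down at |log2fc| = 2, mean >= 100
    de_names = [ref_names[i] for i in rng.choice(len(ref_names), size=10, replace=False)]
    for name in ref_names:
        if name in de_names[:5]:
            lfc, mean = 2.0, float(rng.integers(100, 500))
        elif name in de_names[5:]:
            lfc, mean = -2.0, float(rng.integers(100, 500))
        else:
            lfc = 0.0
            mean = float(np.round(rng.lognormal(mean=5.0, sigma=1.0))) + 12.0
        rows.append({"id": name, "kind": "conserved", "sequence": reference[name],
                     "mean": mean, "lfc_1h": lfc, "lfc_6h": lfc, "lfc_12h": lfc})
    for i, hp in enumerate(hairpins):
        lfc = [2.0, -2.0][i % 2] if i < 4 else 0.0
        rows.append({"id": hp.name, "kind": "novel", "sequence": hp.mature_seq,
                     "mean": float(rng.integers(40, 90)),
                     "lfc_1h": lfc, "lfc_6h": lfc, "lfc_12h": lfc})
        if hp.has_star_reads:
            rows.append({"id": f"{hp.name}_star", "kind": "star", "sequence": hp.star_seq,
                         "mean": 3.0, "lfc_1h": 0.0, "lfc_6h": 0.0, "lfc_12h": 0.0})
    for name in sorted(decoys):
        ln = int(rng.integers(18, 29))
        start = int(rng.integers(0, len(decoys[name]) - ln))
        rows.append({"id": f"{name}_frag", "kind": "ncrna",
                     "sequence": decoys[name][start : start + ln],
                     "mean": float(rng.integers(200, 800)),
                     "lfc_1h": 0.0, "lfc_6h": 0.0, "lfc_12h": 0.0})
    # background genomic tags: mappable but not hairpins; exercise specificity
    chrom_names = sorted(genome)
    spans = {(hp.chrom, hp.start - 400, hp.end + 400) for hp in hairpins}
    added = 0
    while added < 5:
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        ln = int(rng.integers(18, 31))
        start = int(rng.integers(0, len(genome[chrom]) - ln))
        if any(c == chrom and s <= start <= e for c, s, e in spans):
            continue
        seq = genome[chrom][start : start + ln]
        if seq.count("A") / ln >= 0.8 or _count_occurrences(genome, seq) != 1:
            continue
        added += 1
        rows.append({"id": f"bgtag{added:02d}", "kind": "background", "sequence": seq,
                     "mean": float(rng.integers(20, 50)),
                     "lfc_1h": 0.0, "lfc_6h": 0.0, "lfc_12h": 0.0})
    df = pd.DataFrame(rows).set_index("id")
    if df["sequence"].duplicated().any():
        raise RuntimeError("duplicate planted tag sequences in expression truth")
    return df


def simulate_counts(
    expression: pd.DataFrame,
    dispersion: float = 0.0,
    seed: int = 0,
    library_sizes: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Count matrix (rows = expression ids, columns = libraries).

    Per-library means are the truth means scaled by the planted fold change
    (2^lfc at 1 h/6 h/12 h, unscaled at 0 h), optionally rescaled so column
    means sum to ``library_sizes``.  ``dispersion`` = 0 gives the
    deterministic zero-noise limit (counts = rounded means); dispersion > 0
    draws negative-binomial counts with size 1/dispersion.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    means = pd.DataFrame(index=expression.index)
    means["0h"] = expression["mean"]
    for tp in TIMEPOINTS:
        means[tp] = expression["mean"] * np.power(2.0, expression[f"lfc_{tp}"])
    if library_sizes is not None:
        for lib in means.columns:
            if library_sizes[lib] <= 0:
                raise ValueError("library sizes must be positive")
            means[lib] *= library_sizes[lib] / means[lib].sum()
    if dispersion == 0:
        counts = np.rint(means.values)
    else:
        size = 1.0 / dispersion
        p = size / (size + means.values)
        counts = rng.negative_binomial(size, p)
    return pd.DataFrame(counts.astype(np.int64), index=means.index, columns=means.columns)


def simulate_reads(
    counts: pd.DataFrame,
    truth: TruthSet,
    out_paths: dict[str, str],
    adapter3: str = DEFAULT_ADAPTER3,
    contamination_rates: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    read_len: int = 36,
) -> dict[str, dict[str, int]]:
    """Write one FASTQ per library and return per-class true read counts.

    Clean reads are insert + 3' adapter truncated to ``read_len`` at constant
    Q40; contaminant classes are generated per the accounting definitions
    (low mean quality; no adapter occurrence; poly-A insert; insert < 18 nt)
    at the requested fractions of the raw total, deterministically rounded.
    """
    if len(adapter3) < 8:
        raise ValueError("adapter must be >= 8 nt")
    rates = contamination_rates if contamination_rates is not None else truth.contamination_rates
    rng = np.random.default_rng(seed)
    seqs = truth.expression["sequence"]
    hi_q = "I" * read_len
    lo_q = "+" * read_len  # Phred 10
    class_truth: dict[str, dict[str, int]] = {}
    for lib in counts.columns:
        frac = rates.get(lib, {c: 0.0 for c in ("low_quality", "invalid_adapter", "poly_a", "short")})
        clean_total = int(counts[lib].sum())
        clean_frac = 1.0 - sum(frac.values())
        raw_total = int(round(clean_total / clean_frac)) if clean_total else 0
        n_class = {cls: int(round(raw_total * f)) for cls, f in frac.items()}
        with open(out_paths[lib], "w") as fh:
            for rid, c in counts[lib].items():
                insert = seqs.loc[rid]
                read = (insert + adapter3)[:read_len]
                qual = hi_q[: len(read)]
                for i in range(int(c)):
                    fh.write(f"@{lib}|{rid}|{i}\n{read}\n+\n{qual}\n")
            for i in range(n_class["low_quality"]):
                read = (_rand_insert(rng, int(rng.integers(18, 31))) + adapter3)[:read_len]
                fh.write(f"@{lib}|lowq|{i}\n{read}\n+\n{lo_q[: len(read)]}\n")
            for i in range(n_class["invalid_adapter"]):
                while True:
                    read = _rand_insert(rng, read_len)
                    if trim_adapter(read, adapter3) is None:
                        break
                fh.write(f"@{lib}|noadapt|{i}\n{read}\n+\n{hi_q}\n")
            for i in range(n_class["poly_a"]):
                read = ("A" * int(rng.integers(18, 26)) + adapter3)[:read_len]
                fh.write(f"@{lib}|polya|{i}\n{read}\n+\n{hi_q[: len(read)]}\n")
            for i in range(n_class["short"]):
                read = (_rand_insert(rng, int(rng.integers(8, 18))) + adapter3)[:read_len]
                fh.write(f"@{lib}|short|{i}\n{read}\n+\n{hi_q[: len(read)]}\n")
        class_truth[lib] = {"raw_total": clean_total + sum(n_class.values()),
                            "clean": clean_total, **n_class}
    truth.read_class_truth = class_truth
    return class_truth


def simulate_qpcr(
    true_log2fc: pd.DataFrame,
    noise_sd: float = 0.2,
    seed: int = 0,
    replicates: int = 3,
    calibrator: str = "0h",
) -> pd.DataFrame:
    """Ct table (target + U6 reference) whose ddCt reproduces the planted
    log2 fold changes up to zero-mean Gaussian noise of ``noise_sd`` cycles.
    ``true_log2fc`` is indexed by miRNA with one column per timepoint."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for mirna in true_log2fc.index:
        base = 22.0 + float(rng.uniform(-2, 4))
        for tp in (calibrator, *true_log2fc.columns):
            lfc = 0.0 if tp == calibrator else float(true_log2fc.at[mirna, tp])
            for rep in range(1, replicates + 1):
                rows.append({
                    "mirna": mirna,
                    "timepoint": tp,
                    "replicate": rep,
                    "ct_target": base - lfc + float(rng.normal(0, noise_sd)),
                    "ct_reference": 18.0 + float(rng.normal(0, noise_sd)),
                })
    return pd.DataFrame(rows)
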