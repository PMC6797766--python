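from types import SimpleNamespace

import pytest

from srnamir import fold, novel, simdata
from srnamir._seq import revcomp
from srnamir.annotate import Locus


@pytest.fixture(scope="module")
def planted():
    """One constructed-to-pass hairpin with its designed fold."""
    design = simdata.plant_hairpin(5, mature_len=21, span=160)
    folded = fold.fold_mfe(design.precursor)
    return design, folded


class TestExtractPrecursor:
    def _genome(self):
        import numpy as np

        rng = np.random.default_rng(11)
        return {"chr1": simdata._rand_seq(rng, 2000)}

    def test_centred_locus_gives_windows_containing_mature(self):
        genome = self._genome()
        locus = Locus("chr1", 1001, 1021, "+")
        mature = genome["chr1"][1000:1021]
        windows = novel.extract_precursor_candidates(locus, genome)
        assert len(windows) == 3
        for w in windows:
            assert w.sequence[w.mature_offset : w.mature_offset + w.mature_len] == mature
            assert len(w.sequence) <= novel.MAX_PRECURSOR

    def test_window_clipped_at_chromosome_start(self):
        genome = self._genome()
        locus = Locus("chr1", 11, 31, "+")
        windows = novel.extract_precursor_candidates(locus, genome)
        assert all(w.start >= 1 for w in windows)
        assert any(len(w.sequence) < novel.MAX_PRECURSOR for w in windows)

    def test_minus_strand_window_contains_mature_verbatim(self):
        genome = self._genome()
        mature_plus = genome["chr1"][1000:1021]
        locus = Locus("chr1", 1001, 1021, "-")
        for w in novel.extract_precursor_candidates(locus, genome):
            assert w.sequence[w.mature_offset : w.mature_offset + w.mature_len] == revcomp(mature_plus)

    def test_locus_outside_genome_is_error(self):
        with pytest.raises(ValueError):
            novel.extract_precursor_candidates(Locus("chrX", 1, 21, "+"), self._genome())


class TestFindStar:
    def test_planted_partner_interval_recovered(self, planted):
        design, folded = planted
        star = novel.find_star(folded, design.mature_offset, design.mature_len)
        assert star is not None
        assert star.arm == "5p"
        assert (star.start, star.length) == (design.star_offset, design.star_len)

    def test_star_of_star_is_the_mature(self, planted):
        """Treating the star as the query exercises the 3' arm branch: the
        Dicer shift applied twice recovers the mature interval exactly."""
        design, folded = planted
        star = novel.find_star(folded, design.star_offset, design.star_len)
        assert star is not None
        assert star.arm == "3p"
        assert (star.start, star.length) == (design.mature_offset, design.mature_len)

    def test_mature_spanning_loop_gives_none(self, planted):
        design, folded = planted
        n = len(design.precursor)
        mid = n // 2 - 10
        assert novel.find_star(folded, mid, 21) is None


class TestDuplexCheck:
    def test_perfect_duplex_passes(self, planted):
        design, folded = planted
        star = novel.find_star(folded, design.mature_offset, design.mature_len)
        mm, bulges, (om, os_), ok = novel.duplex_check(
            folded, design.mature_offset, design.mature_len, star)
        assert (mm, bulges) == (0, 0)
        assert om >= 1 and os_ >= 1
        assert ok

    def test_three_mismatches_fail_strict_boundary(self):
        design = None
        import numpy as np

        rng = np.random.default_rng(17)
        for _ in range(20):
            d = simdata.plant_hairpin(rng, mature_len=22, span=170, stem_mismatches=3)
            folded = fold.fold_mfe(d.precursor)
            star = novel.find_star(folded, d.mature_offset, d.mature_len)
            if star is None:
                continue
            mm, bulges, _, ok = novel.duplex_check(folded, d.mature_offset, d.mature_len, star)
            if mm == 3:
                design = d
                assert not ok
                break
        assert design is not None, "no draw realized exactly 3 mismatches"

    def test_two_asymmetric_bulge_runs_fail(self):
        import numpy as np

        rng = np.random.default_rng(23)
        seen = False
        for _ in range(30):
            d = simdata.plant_hairpin(rng, mature_len=22, span=180, bulges=2, bulge_len=3)
            folded = fold.fold_mfe(d.precursor)
            star = novel.find_star(folded, d.mature_offset, d.mature_len)
            if star is None:
                continue
            mm, bulges, _, ok = novel.duplex_check(folded, d.mature_offset, d.mature_len, star)
            if bulges >= 2:
                assert not ok
                seen = True
                break
        assert seen, "no draw realized two asymmetric bulge runs"


class TestEvaluateAndReport:
    def test_planted_hairpin_without_star_reads_fails_on_star_rule(self, demo):
        truth = demo.truth
        hp = next(h for h in truth.hairpins if not h.has_star_reads)
        locus = Locus(hp.chrom, hp.start + hp.mature_offset,
                      hp.start + hp.mature_offset + len(hp.mature_seq) - 1, hp.strand)
        if hp.strand == "-":
            e = hp.end - hp.mature_offset
            locus = Locus(hp.chrom, e - len(hp.mature_seq) + 1, e, hp.strand)
        windows = novel.extract_precursor_candidates(locus, truth.genome)
        cands = novel.assess_windows(locus, windows, {hp.mature_seq: 50})
        assert all(c.verdict == "fail" for c in cands)
        assert any("star_reads" in c.failed_rules for c in cands)

    def test_report_lengths_equal_mature_lengths(self):
        rows = [
            ("A01", 13241536, 13241782, "+", "ATTTTGAGCATGTGGCTAGCTTT", 23),
            ("A03", 32323869, 32324023, "+", "ATTCATGCTTGACTACATCA", 20),
        ]
        cands = [
            SimpleNamespace(
                locus=Locus(c, s, e, st),
                mature_seq=seq,
            )
            for c, s, e, st, seq, _ in rows
        ]
        report = novel.report_novel(cands)
        assert list(report["length"]) == [ln for *_, ln in rows]
        assert list(report["name"]) == ["novel-mir001", "novel-mir002"]
        assert report.loc[0, "location"] == "A01:13241536-13241782"

    def test_empty_candidate_set_gives_header_only(self):
        report = novel.report_novel([])
        assert len(report) == 0
        assert list(report.columns) == ["name", "location", "length", "strand", "mature_sequence"]

    def test_verdict_is_pure(self, planted):
        design, folded = planted
        locus = Locus("chr", 1, design.mature_len, "+")
        w = novel.PrecursorWindow("chr", 1, len(design.precursor), "+", design.precursor,
                                  design.mature_offset, design.mature_len)
        tags = {design.mature_seq: 10, design.star_seq: 2}
        a = novel.assess_windows(locus, [w], tags)
        b = novel.assess_windows(locus, [w], tags)
        assert [c.verdict for c in a] == [c.verdict for c in b]
        assert a[0].verdict == "pass"
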