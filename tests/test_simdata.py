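import numpy as np
import pandas as pd
import pytest

from srnamir import fold, novel, readqc, simdata
from srnamir._seq import revcomp


class TestMakeGenome:
    def test_size_contract_and_truth_listing(self, tmp_path):
        genome, truth = simdata.make_genome(1, n_chrom=2, chrom_len=50_000)
        assert len(genome) == 2
        assert all(len(s) == 50_000 for s in genome.values())
        assert len(truth.hairpins) == 10
        for hp in truth.hairpins:
            assert 120 <= hp.end - hp.start + 1 <= 320

    def test_seed_determinism_bytes(self):
        g1, t1 = simdata.make_genome(5)
        g2, t2 = simdata.make_genome(5)
        assert g1 == g2
        assert t1.expression.equals(t2.expression)
        assert [h.precursor_seq for h in t1.hairpins] == [h.precursor_seq for h in t2.hairpins]

    def test_different_seeds_move_hairpin_loci(self):
        _, t1 = simdata.make_genome(1)
        _, t2 = simdata.make_genome(2)
        assert [(h.chrom, h.start) for h in t1.hairpins] != [(h.chrom, h.start) for h in t2.hairpins]

    def test_capacity_error_names_the_limit(self):
        specs = [dict(name=f"h{i}", mature_len=21, span=300, mismatches=0, bulges=0,
                      star_reads=True, expect="pass") for i in range(20)]
        with pytest.raises(ValueError, match="capacity"):
            simdata.make_genome(1, n_chrom=1, chrom_len=5000, hairpin_specs=specs)

    def test_planted_mature_on_recorded_strand(self):
        genome, truth = simdata.make_genome(3)
        for hp in truth.hairpins:
            segment = genome[hp.chrom][hp.start - 1 : hp.end]
            if hp.strand == "-":
                segment = revcomp(segment)
            assert segment == hp.precursor_seq
            assert hp.mature_seq in segment


class TestPlantHairpin:
    def test_constructed_to_pass(self):
        d = simdata.plant_hairpin(11, mature_len=21, stem_mismatches=0, bulges=0)
        folded = fold.fold_mfe(d.precursor)
        star = novel.find_star(folded, d.mature_offset, d.mature_len)
        assert star is not None
        *_, ok = novel.duplex_check(folded, d.mature_offset, d.mature_len, star)
        assert ok

    def test_star_is_duplex_partner_with_two_nt_shift(self):
        d = simdata.plant_hairpin(13, mature_len=22, span=180)
        partners = [j for i, j in d.designed_pairs
                    if d.mature_offset <= i < d.mature_offset + d.mature_len]
        assert d.star_offset == min(partners) + 2
        assert d.star_offset + d.star_len - 1 == max(partners) + 2

    def test_mfei_of_planted_hairpins_in_typical_band(self):
        rng = np.random.default_rng(19)
        for _ in range(5):
            d = simdata.plant_hairpin(rng, mature_len=21, loop_len=8, span=200)
            folded = fold.fold_mfe(d.precursor)
            assert folded.mfei >= 0.8

    def test_contradictory_parameters_error(self):
        with pytest.raises(ValueError):
            simdata.plant_hairpin(1, mature_len=18, stem_mismatches=5, bulges=4)
        with pytest.raises(ValueError):
            simdata.plant_hairpin(1, mature_len=17)
        with pytest.raises(ValueError):
            simdata.plant_hairpin(1, loop_len=2)


@pytest.fixture(scope="module")
def expression():
    _, truth = simdata.make_genome(7)
    return truth.expression


class TestSimulateCounts:

    def test_zero_dispersion_gives_rounded_means(self, expression):
        counts = simdata.simulate_counts(expression, dispersion=0.0)
        expect_0h = np.rint(expression["mean"].values)
        assert (counts["0h"].values == expect_0h).all()
        expect_1h = np.rint(expression["mean"].values * 2.0 ** expression["lfc_1h"].values)
        assert (counts["1h"].values == expect_1h).all()

    def test_seed_determinism(self, expression):
        a = simdata.simulate_counts(expression, dispersion=0.1, seed=3)
        b = simdata.simulate_counts(expression, dispersion=0.1, seed=3)
        assert a.equals(b)

    def test_negative_dispersion_rejected(self, expression):
        with pytest.raises(ValueError):
            simdata.simulate_counts(expression, dispersion=-0.1)

    def test_column_sums_track_requested_library_sizes(self, expression):
        sizes = {lib: 30_000.0 for lib in simdata.LIBRARIES}
        sums = []
        for seed in range(60):
            c = simdata.simulate_counts(expression, dispersion=0.05, seed=seed,
                                        library_sizes=sizes)
            sums.append(c.sum(axis=0).values)
        sums = np.asarray(sums, dtype=float)
        # mean column sum within 3 SD-of-the-mean of the target depth
        for j in range(sums.shape[1]):
            se = sums[:, j].std(ddof=1) / np.sqrt(sums.shape[0])
            assert abs(sums[:, j].mean() - 30_000.0) < 3 * max(se, 1.0)


class TestSimulateReads:
    def test_zero_contamination_reports_all_clean(self, tmp_path):
        _, truth = simdata.make_genome(9)
        counts = simdata.simulate_counts(truth.expression)
        paths = {lib: str(tmp_path / f"{lib}.fastq") for lib in simdata.LIBRARIES}
        zero = {lib: {c: 0.0 for c in ("low_quality", "invalid_adapter", "poly_a", "short")}
                for lib in simdata.LIBRARIES}
        simdata.simulate_reads(counts, truth, paths, contamination_rates=zero, seed=1)
        reads = readqc.classify_library(readqc.parse_fastq(paths["0h"]))
        table = readqc.qc_accounting({"0h": reads})
        assert table.at["0h", "clean_pct"] == 100.0

    def test_per_class_counts_match_recorded_truth(self, tmp_path):
        _, truth = simdata.make_genome(9)
        counts = simdata.simulate_counts(truth.expression)
        paths = {lib: str(tmp_path / f"{lib}.fastq") for lib in simdata.LIBRARIES}
        class_truth = simdata.simulate_reads(counts, truth, paths, seed=1)
        reads = readqc.classify_library(readqc.parse_fastq(paths["12h"]))
        table = readqc.qc_accounting({"12h": reads})
        for cls in ("low_quality", "invalid_adapter", "poly_a", "short", "clean"):
            assert table.at["12h", cls] == class_truth["12h"][cls]

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        _, truth = simdata.make_genome(9)
        counts = simdata.simulate_counts(truth.expression)
        p1 = {lib: str(tmp_path / f"a_{lib}.fastq") for lib in simdata.LIBRARIES}
        p2 = {lib: str(tmp_path / f"b_{lib}.fastq") for lib in simdata.LIBRARIES}
        simdata.simulate_reads(counts, truth, p1, seed=4)
        simdata.simulate_reads(counts, truth, p2, seed=4)
        for lib in simdata.LIBRARIES:
            assert open(p1[lib]).read() == open(p2[lib]).read()


class TestSimulateQpcr:
    def test_seed_determinism(self):
        lfc = pd.DataFrame({"1h": [1.0]}, index=["m"])
        a = simdata.simulate_qpcr(lfc, noise_sd=0.3, seed=5)
        b = simdata.simulate_qpcr(lfc, noise_sd=0.3, seed=5)
        assert a.equals(b)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simdata.simulate_qpcr(pd.DataFrame({"1h": [1.0]}, index=["m"]), noise_sd=-1)
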