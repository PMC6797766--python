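import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

from srnamir import diffexpr
from srnamir.diffexpr import ac_pmf, ac_tails, bonferroni, call_de


class TestNormalizeFloorFilter:
    def test_reads_per_million(self):
        counts = pd.DataFrame({"a": [250, 0]}, index=["m1", "m2"])
        norm = diffexpr.normalize(counts, {"a": 25_000_000})
        assert norm.at["m1", "a"] == pytest.approx(10.0)
        assert norm.at["m2", "a"] == 0.0

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            diffexpr.normalize(pd.DataFrame({"a": [1]}), {"a": 0})

    def test_floor_replaces_exact_zeros_only(self):
        norm = pd.DataFrame({"a": [0.0, 0.005, 2.0]})
        floored = diffexpr.floor_zeros(norm)
        assert list(floored["a"]) == [0.01, 0.005, 2.0]

    def test_floor_rejects_negative_values(self):
        with pytest.raises(ValueError):
            diffexpr.floor_zeros(pd.DataFrame({"a": [-1.0]}))

    @pytest.mark.parametrize(
        "values,kept",
        [((0.5, 0.5, 0.5, 0.5), False), ((0.5, 0.5, 2.0, 0.5), True), ((1.0, 0, 0, 0), True)],
    )
    def test_low_expression_filter(self, values, kept):
        norm = pd.DataFrame([values], columns=list("abcd"))
        assert bool(diffexpr.low_expression_filter(norm).iloc[0]) is kept

    def test_log2fc_examples(self):
        assert diffexpr.log2fc(2, 1) == pytest.approx(1.0)
        assert diffexpr.log2fc(5, 5) == 0.0
        assert diffexpr.log2fc(0.01, 1) == pytest.approx(-6.6438, abs=1e-3)
        with pytest.raises(ValueError):
            diffexpr.log2fc(0, 1)


class TestAcStatistic:
    def test_analytic_values_equal_depths(self):
        assert ac_pmf(0, 0, 1e6, 1e6) == pytest.approx(0.5)
        assert ac_pmf(0, 2, 1e6, 1e6) == pytest.approx(0.125)

    def test_pmf_sums_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = int(rng.integers(0, 200))
            n1 = float(rng.integers(10**5, 10**7))
            n2 = float(rng.integers(10**5, 10**7))
            mean = (x + 1) * n2 / n1
            sd = np.sqrt((x + 1) * (n2 / n1) * (1 + n2 / n1))
            ys = np.arange(0, int(mean + 40 * sd) + 60)
            total = float(np.exp(diffexpr._log_pmf(ys, x, n1, n2)).sum())
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_negative_binomial_form(self):
        """The printed formula is the NB(x+1, N1/(N1+N2)) pmf in y - checked
        against scipy as an independent route."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            x = int(rng.integers(0, 300))
            y = int(rng.integers(0, 300))
            n1 = float(rng.integers(10**4, 10**7))
            n2 = float(rng.integers(10**4, 10**7))
            expect = nbinom.pmf(y, x + 1, n1 / (n1 + n2))
            assert ac_pmf(y, x, n1, n2) == pytest.approx(expect, rel=1e-10, abs=1e-300)

    def test_no_overflow_at_large_counts(self):
        c, d, p = ac_tails(10**7, 10**7 + 1000, 2e7, 2e7)
        assert 0 <= p <= 1
        assert np.isfinite([c, d]).all()

    def test_tails_identity_and_single_term(self):
        # C + D double-counts exactly the observed point
        for x, y in [(5, 5), (10, 3), (0, 7)]:
            c, d, _ = ac_tails(x, y, 3e6, 4e6)
            assert c + d == pytest.approx(1.0 + ac_pmf(y, x, 3e6, 4e6), abs=1e-12)
        # y_obs = 0: lower tail is the single term p(0|x)
        c, _, _ = ac_tails(4, 0, 1e6, 1e6)
        assert c == pytest.approx(ac_pmf(0, 4, 1e6, 1e6), abs=1e-15)

    def test_symmetric_case_p_near_one(self):
        c, d, p = ac_tails(50, 50, 1e6, 1e6)
        assert p == pytest.approx(1.0)

    def test_extreme_upper_tail_is_tiny(self):
        _, d, _ = ac_tails(0, 50, 1e6, 1e6)
        assert d < 1e-10

    def test_tail_symmetry_under_library_exchange(self):
        """Exchanging (x, N1) with (y, N2) maps C onto D up to the shared
        boundary term (both tails include the observed count)."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = int(rng.integers(0, 400))
            y = int(rng.integers(0, 400))
            n1 = float(rng.integers(10**5, 10**7))
            n2 = float(rng.integers(10**5, 10**7))
            c1, d1, _ = ac_tails(x, y, n1, n2)
            c2, d2, _ = ac_tails(y, x, n2, n1)
            boundary = ac_pmf(x, y, n2, n1)
            assert c1 == pytest.approx(d2 - boundary, abs=1e-10)
            assert d1 == pytest.approx(c2 + ac_pmf(y, x, n1, n2), abs=1e-10)

    def test_tails_against_scipy_cdf_sf(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            x = int(rng.integers(0, 200))
            y = int(rng.integers(0, 200))
            n1, n2 = 2.5e6, 3.1e6
            c, d, _ = ac_tails(x, y, n1, n2)
            p = n1 / (n1 + n2)
            assert c == pytest.approx(nbinom.cdf(y, x + 1, p), rel=1e-9, abs=1e-12)
            assert d == pytest.approx(nbinom.sf(y - 1, x + 1, p), rel=1e-9, abs=1e-12)


class TestBonferroniAndCalls:
    def test_bonferroni_examples(self):
        assert bonferroni([0.01], m=10)[0] == pytest.approx(0.1)
        assert bonferroni([0.5], m=3)[0] == 1.0
        assert bonferroni([]).size == 0
        with pytest.raises(ValueError):
            bonferroni([1.5])

    @pytest.mark.parametrize(
        "lfc,p,expect",
        [(2.0, 0.001, "up"), (-0.5, 0.001, "ns"), (3.0, 0.2, "ns"), (-2.0, 0.01, "down")],
    )
    def test_call_de(self, lfc, p, expect):
        assert call_de(lfc, p, fc_cut=1.0, p_cut=0.05) == expect


class TestDeTable:
    def test_planted_fold_change_recovered(self):
        counts = pd.DataFrame(
            {"0h": [100, 500, 2], "1h": [400, 500, 1]}, index=["up2", "flat", "rare"]
        )
        totals = {"0h": 10_000_000, "1h": 10_000_000}  # "rare" falls below 1 RPM
        de = diffexpr.de_table(counts, totals, "0h", "1h")
        assert "rare" not in de.index  # below 1 RPM everywhere
        assert de.at["up2", "log2fc"] == pytest.approx(2.0)
        assert de.at["up2", "call"] == "up"
        assert de.at["flat", "call"] == "ns"
        assert de.at["up2", "p_bonferroni"] == pytest.approx(
            min(1.0, len(de) * de.at["up2", "p_raw"])
        )

    def test_volcano_frame_columns(self):
        counts = pd.DataFrame({"0h": [100], "1h": [400]}, index=["m"])
        de = diffexpr.de_table(counts, {"0h": 10**6, "1h": 10**6}, "0h", "1h")
        v = diffexpr.volcano_frame(de)
        assert {"log2fc", "neg_log10_p", "call"} <= set(v.columns)
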