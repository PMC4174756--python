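import numpy as np
import pandas as pd
import pytest

from chipctrl.binning import BinnedCounts
from chipctrl.enrichment import (correlate_expression, count_distribution,
                                 count_read_centers, differential_screen,
                                 enrichment_rpkm, expression_rpkm, ma_stats,
                                 promoter_interval)
from chipctrl.io_formats import GeneModel, ReadRecord


def _counts(vec):
    vec = np.asarray(vec, dtype=np.int64)
    return BinnedCounts("s", 1000, {"chr1": vec}, int(vec.sum()), {"chr1": len(vec) * 1000})


class TestCountDistribution:
    def test_raw_and_normalized(self):
        d = count_distribution(_counts([0, 0, 1, 2, 2]))
        assert dict(zip(d["count"], d["frequency"])) == {0: 2, 1: 1, 2: 2}
        dn = count_distribution(_counts([0, 0, 1, 2, 2]), normalize=True)
        assert dict(zip(dn["count"], dn["frequency"])) == {0: 0.4, 1: 0.2, 2: 0.4}
        assert dn["frequency"].sum() == pytest.approx(1.0)


class TestRpkmRules:
    def test_expression_pseudocount_on_cpm(self):
        # 10 reads, library 1e6, exon 2 kb: (10 + 1) / 2 = 5.5
        assert expression_rpkm(np.array([10]), np.array([2000]), 10**6)[0] == pytest.approx(5.5)

    def test_expression_floor_is_one_per_kb(self):
        assert expression_rpkm(np.array([0]), np.array([1000]), 10**6)[0] == pytest.approx(1.0)

    def test_expression_monotone_in_count(self):
        lo, hi = expression_rpkm(np.array([5, 10]), np.array([1000, 1000]), 10**6)
        assert hi > lo

    def test_enrichment_pseudocount_on_rpkm(self):
        # 20 reads, library 1e7, span 4 kb: 20/10/4 + 0.5 = 1.0
        assert enrichment_rpkm(np.array([20]), np.array([4000]), 10**7)[0] == pytest.approx(1.0)

    def test_enrichment_floor_is_half(self):
        assert enrichment_rpkm(np.array([0]), np.array([3000]), 10**6)[0] == pytest.approx(0.5)

    @pytest.mark.parametrize("fn", [expression_rpkm, enrichment_rpkm])
    def test_zero_length_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(np.array([1]), np.array([0]), 10**6)


class TestPromoter:
    def test_four_kb_centered_on_strand_aware_tss(self):
        plus = GeneModel("g", "chr1", 10_000, 20_000, "+", 5000)
        minus = GeneModel("g", "chr1", 10_000, 20_000, "-", 5000)
        assert promoter_interval(plus, 1_000_000) == ("chr1", 8000, 12_000)
        assert promoter_interval(minus, 1_000_000) == ("chr1", 17_999, 21_999)

    def test_clipped_at_contig_edges(self):
        near_start = GeneModel("g", "chr1", 500, 3000, "+", 1000)
        assert promoter_interval(near_start, 1_000_000) == ("chr1", 0, 2500)


class TestMAStats:
    def test_equal_cpm_gives_zero_m(self):
        ma = ma_stats(np.array([10]), np.array([20]), 10**6, 2 * 10**6)
        assert ma["M"][0] == pytest.approx(0.0)

    def test_swapping_samples_negates_m_preserves_a(self):
        x, y = np.array([40, 3]), np.array([10, 9])
        lib = 10**6
        fwd = ma_stats(x, y, lib, lib)
        rev = ma_stats(y, x, lib, lib)
        np.testing.assert_allclose(fwd["M"], -rev["M"])
        np.testing.assert_allclose(fwd["A"], rev["A"])

    def test_fourfold_cpm_is_m_two(self):
        ma = ma_stats(np.array([4000]), np.array([1000]), 10**6, 10**6, pseudocount_cpm=0)
        assert ma["M"][0] == pytest.approx(2.0)


class TestDifferentialScreen:
    def test_balanced_split_gives_p_one(self):
        out = differential_screen(np.array([5]), np.array([5]), 10**6, 10**6)
        assert out["p_value"][0] == pytest.approx(1.0)

    def test_one_sided_extreme_matches_tail_sum(self):
        # x=10, y=0, equal libraries: two-sided p = 2 * 0.5^10
        out = differential_screen(np.array([10]), np.array([0]), 10**6, 10**6)
        assert out["p_value"][0] == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_empty_units_excluded_from_testing_and_bh(self):
        out = differential_screen(np.array([0, 10]), np.array([0, 0]), 10**6, 10**6)
        assert np.isnan(out["p_value"][0]) and np.isnan(out["fdr"][0])
        # with a single tested unit BH leaves its p unchanged
        assert out["fdr"][1] == pytest.approx(out["p_value"][1])

    def test_bh_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(20, size=300)
        y = rng.poisson(20, size=300)
        out = differential_screen(x, y, 10**6, 10**6).dropna()
        ordered = out.sort_values("p_value")["fdr"].to_numpy()
        assert np.all(np.diff(ordered) >= -1e-12)

    def test_method_tag_present(self):
        out = differential_screen(np.array([1]), np.array([2]), 10**6, 10**6)
        assert (out["method"] == "exact-binomial").all()


class TestCountReadCenters:
    def test_center_rule_at_interval_boundary(self):
        reads = [ReadRecord("chr1", 95, 105, "+", 30),   # center 99 -> outside
                 ReadRecord("chr1", 96, 106, "+", 30),   # center 100 -> inside
                 ReadRecord("chr2", 100, 120, "+", 30)]  # other contig
        out = count_read_centers(reads, [("chr1", 100, 200)])
        assert out[0] == 1


def _table(expr, mark, ctrl):
    return pd.DataFrame({
        "expression_rpkm": expr,
        "mark_body": mark, "ctrl_body": ctrl,
        "mark_promoter": mark, "ctrl_promoter": ctrl,
    }, index=[f"g{i}" for i in range(len(expr))])


class TestCorrelateExpression:
    def test_perfect_correlation_and_anticorrelation(self):
        expr = np.array([1.0, 2.0, 4.0, 8.0])
        assert correlate_expression(_table(expr, expr, expr * 0 + 1), "mark") == pytest.approx(1.0)
        assert correlate_expression(_table(expr, 1 / expr, expr * 0 + 1), "mark") == pytest.approx(-1.0)

    def test_control_removes_positive_background(self):
        # mark signal ~ e^-1 times a shared positive background ~ e^0.5:
        # dividing by a control carrying the background strengthens the
        # anti-correlation
        rng = np.random.default_rng(8)
        e = np.exp(rng.normal(1.0, 1.0, 200))
        background = e**0.5 * np.exp(rng.normal(0, 0.2, 200))
        mark = e**-1.0 * background * np.exp(rng.normal(0, 0.2, 200))
        t = _table(e, mark, background)
        r_plain = correlate_expression(t, "mark")
        r_ratio = correlate_expression(t, "mark", "ctrl")
        assert r_plain < 0
        assert r_ratio < r_plain

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            correlate_expression(_table(np.array([1., 2., 3.]),
                                        np.array([1., 1., 1.]),
                                        np.array([1., 1., 1.])), "mark")

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValueError, match="3 genes"):
            correlate_expression(_table(np.array([1., 2.]), np.array([1., 2.]),
                                        np.array([1., 1.])), "mark")
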