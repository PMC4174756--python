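import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipctrl.binning import (BinnedCounts, bin_coverage_rpkm, bin_reads,
                              read_bincounts, rebin, write_bincounts)
from chipctrl.io_formats import ReadRecord

LENGTHS = {"chr1": 10_000}


def _reads(*intervals):
    return [ReadRecord("chr1", s, e, "+", 30) for s, e in intervals]


read_lists = st.lists(
    st.tuples(st.integers(0, 9_000), st.integers(1, 500)).map(lambda t: (t[0], t[0] + t[1])),
    max_size=50)


class TestBinReads:
    def test_center_rule_even_length_read(self):
        # read [950, 1050): center floor((950+1049)/2) = 999 -> bin 0 at 1 kb
        binned = bin_reads(_reads((950, 1050)), LENGTHS, 1000)
        assert binned.counts["chr1"][0] == 1
        assert binned.counts["chr1"][1] == 0

    def test_boundary_center_goes_to_next_bin(self):
        binned = bin_reads(_reads((1000, 1001)), LENGTHS, 1000)
        assert binned.counts["chr1"][1] == 1

    @settings(max_examples=25, deadline=None)
    @given(read_lists)
    def test_conservation_and_permutation_invariance(self, intervals):
        reads = _reads(*intervals)
        binned = bin_reads(reads, LENGTHS, 100)
        assert binned.total() == len(reads) == binned.library_size
        shuffled = bin_reads(list(reversed(reads)), LENGTHS, 100)
        np.testing.assert_array_equal(binned.counts["chr1"], shuffled.counts["chr1"])

    def test_unknown_contig_and_off_contig_center_rejected(self):
        with pytest.raises(ValueError, match="unknown contig"):
            bin_reads([ReadRecord("chrX", 0, 50, "+", 30)], LENGTHS, 100)
        with pytest.raises(ValueError, match="outside contig"):
            bin_reads(_reads((9_990, 10_030)), LENGTHS, 100)


class TestRebin:
    def test_pairwise_sum(self):
        c = BinnedCounts("s", 100, {"chr1": np.array([1, 2, 3, 4])}, 10, {"chr1": 400})
        np.testing.assert_array_equal(rebin(c, 2).counts["chr1"], [3, 7])

    def test_factor_one_is_identity(self):
        c = BinnedCounts("s", 100, {"chr1": np.array([1, 2, 3, 4])}, 10, {"chr1": 400})
        np.testing.assert_array_equal(rebin(c, 1).counts["chr1"], c.counts["chr1"])

    @settings(max_examples=25, deadline=None)
    @given(read_lists, st.sampled_from([2, 5, 10]))
    def test_rebin_equals_direct_binning_at_coarser_width(self, intervals, factor):
        reads = _reads(*intervals)
        coarse = rebin(bin_reads(reads, LENGTHS, 100), factor)
        direct = bin_reads(reads, LENGTHS, 100 * factor)
        np.testing.assert_array_equal(coarse.counts["chr1"], direct.counts["chr1"])
        assert coarse.bin_width == direct.bin_width

    def test_associativity(self):
        c = bin_reads(_reads(*[(i * 37, i * 37 + 40) for i in range(50)]), LENGTHS, 10)
        left = rebin(rebin(c, 2), 5)
        right = rebin(c, 10)
        np.testing.assert_array_equal(left.counts["chr1"], right.counts["chr1"])


class TestRpkm:
    def test_hand_computed_value(self):
        # 10 reads in one 1000 bp bin, library 1e7 -> 10 / 10 / 1 = 1.0 RPKM
        c = BinnedCounts("s", 1000, {"chr1": np.array([10, 0])}, 10_000_000,
                         {"chr1": 2000})
        rpkm = bin_coverage_rpkm(c)["chr1"]
        assert rpkm[0] == pytest.approx(1.0)
        assert rpkm[1] == 0.0

    def test_doubling_library_halves_values(self):
        a = BinnedCounts("s", 1000, {"chr1": np.array([10, 4])}, 1_000_000, {"chr1": 2000})
        b = BinnedCounts("s", 1000, {"chr1": np.array([10, 4])}, 2_000_000, {"chr1": 2000})
        np.testing.assert_allclose(bin_coverage_rpkm(a)["chr1"],
                                   2 * bin_coverage_rpkm(b)["chr1"])

    def test_zero_library_is_error(self):
        c = BinnedCounts("s", 1000, {"chr1": np.array([0, 0])}, 0, {"chr1": 2000})
        with pytest.raises(ValueError):
            bin_coverage_rpkm(c)


def test_bincounts_tsv_roundtrip(tmp_path):
    c = bin_reads(_reads((0, 100), (250, 350), (9_900, 9_950)), LENGTHS, 100)
    write_bincounts(tmp_path / "c.tsv", c)
    back = read_bincounts(tmp_path / "c.tsv")
    assert back.bin_width == c.bin_width
    assert back.library_size == c.library_size
    assert back.contig_lengths == c.contig_lengths
    np.testing.assert_array_equal(back.counts["chr1"], c.counts["chr1"])
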