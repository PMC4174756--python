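import numpy as np
import pytest

from chipctrl.binning import BinnedCounts, bin_reads
from chipctrl.io_formats import GeneModel, ReadRecord
from chipctrl.metagene import (exclude_extreme_genes, gene_coverage_vector,
                               gene_profile_bins, profile_sample,
                               quartile_split, ratio_profile, smooth_profile,
                               tss_profile)


def _gene(gid="g", start=1000, end=2000, strand="+", expr=1.0, contig="chr1"):
    return GeneModel(gid, contig, start, end, strand, (end - start) // 2, expr)


class TestGeneProfileBins:
    def test_plus_strand_tiling(self):
        bins = gene_profile_bins(_gene())
        assert bins.shape == (150, 2)
        np.testing.assert_allclose(bins[0], [0, 20])
        np.testing.assert_allclose(bins[1], [20, 40])
        np.testing.assert_allclose(bins[-1], [2980, 3000])
        # first gene-body bin starts exactly at the gene start
        np.testing.assert_allclose(bins[50], [1000, 1020])

    def test_minus_strand_reverses_order(self):
        fwd = gene_profile_bins(_gene(strand="+"))
        rev = gene_profile_bins(_gene(strand="-"))
        np.testing.assert_allclose(rev, fwd[::-1])

    def test_tiny_gene_rejected(self):
        with pytest.raises(ValueError, match="width"):
            gene_profile_bins(_gene(start=100, end=140))


class TestSmoothing:
    def test_edge_rule_hand_computed(self):
        v = np.zeros(150)
        v[1] = 3.0
        out = smooth_profile(v)
        np.testing.assert_allclose(out[:4], [1.5, 1.0, 1.0, 0.0])

    def test_constant_vector_is_fixed_point(self):
        v = np.full(150, 2.5)
        np.testing.assert_allclose(smooth_profile(v), v)

    def test_interior_sum_preserved(self):
        rng = np.random.default_rng(0)
        v = rng.random(150)
        out = smooth_profile(v)
        # mass only leaks at the two truncated edges
        assert abs(out.sum() - v.sum()) <= v[0] + v[1] + v[-1] + v[-2]


class TestGeneSelection:
    def test_exclusion_is_strictly_greater_than(self):
        genes = [_gene("a", expr=5.0), _gene("b", expr=100.0), _gene("c", expr=100.1)]
        kept = exclude_extreme_genes(genes)
        assert [g.gene_id for g in kept] == ["a", "b"]

    def test_no_extreme_genes_is_identity(self):
        genes = [_gene("a", expr=5.0), _gene("b", expr=7.0)]
        assert exclude_extreme_genes(genes) == genes

    def test_quartiles_rank_order_and_sizes(self):
        genes = [_gene(f"g{i}", expr=float(i)) for i in range(8)]
        groups = quartile_split(list(reversed(genes)))
        assert [[g.gene_id for g in grp] for grp in groups] == [
            ["g0", "g1"], ["g2", "g3"], ["g4", "g5"], ["g6", "g7"]]

    def test_remainder_goes_to_lowest_quartiles(self):
        genes = [_gene(f"g{i}", expr=float(i)) for i in range(10)]
        assert [len(grp) for grp in quartile_split(genes)] == [3, 3, 2, 2]

    def test_ties_broken_by_gene_id(self):
        genes = [_gene(gid, expr=1.0) for gid in ("d", "b", "a", "c")]
        groups = quartile_split(genes)
        assert [grp[0].gene_id for grp in groups] == ["a", "b", "c", "d"]

    def test_fewer_than_four_genes_is_error(self):
        with pytest.raises(ValueError):
            quartile_split([_gene("a"), _gene("b"), _gene("c")])


def _uniform_counts(count_per_bin=5, n_bins=400, width=100):
    vec = np.full(n_bins, count_per_bin, dtype=np.int64)
    return BinnedCounts("s", width, {"chr1": vec}, int(vec.sum()),
                        {"chr1": n_bins * width})


class TestProfiles:
    def test_uniform_coverage_gives_flat_profile(self):
        counts = _uniform_counts()
        genes = [_gene(f"g{i}", start=5000 + i * 8000, end=7000 + i * 8000,
                       expr=float(i + 1)) for i in range(4)]
        expected = 5 / (counts.library_size / 1e6) / 0.1
        for q in (1, 2, 3, 4):
            prof = profile_sample(counts, genes, q)
            np.testing.assert_allclose(prof.values, expected)

    def test_gene_bin_inside_single_genome_bin_contributes_that_rpkm(self):
        vec = np.zeros(400, dtype=np.int64)
        vec[10] = 7  # genome bin [1000, 1100)
        counts = BinnedCounts("s", 100, {"chr1": vec}, 7, {"chr1": 40_000})
        gene = _gene(start=1000, end=2000)
        rpkm_v = 7 / (7 / 1e6) / 0.1
        cov = gene_coverage_vector({"chr1": vec / (7 / 1e6) / 0.1}, gene, 100)
        # gene bins 50..54 ([1000,1020) .. [1080,1100)) lie wholly in that bin
        np.testing.assert_allclose(cov[50:55], rpkm_v)
        assert cov[56] == 0.0

    def test_window_off_contig_excluded(self):
        cov = gene_coverage_vector({"chr1": np.zeros(40)}, _gene(start=500, end=2500), 100)
        assert cov is None

    def test_strand_mirror_symmetry(self):
        # mirroring the genome and flipping every strand mirrors nothing:
        # the strand-oriented profile is identical; odd read lengths keep
        # the floor-center rule exactly mirror-symmetric
        L = 40_000
        rng = np.random.default_rng(3)
        starts = rng.integers(0, L - 120, size=2000)
        reads = [ReadRecord("chr1", int(s), int(s) + 101, "+", 30) for s in starts]
        mirrored = [ReadRecord("chr1", L - r.end, L - r.start, "-", 30) for r in reads]
        genes = [_gene(f"g{i}", start=5000 + i * 8000, end=7000 + i * 8000,
                       strand="+", expr=float(i + 1)) for i in range(4)]
        mgenes = [GeneModel(g.gene_id, g.contig, L - g.end, L - g.start, "-",
                            g.exon_length, g.expression_rpkm) for g in genes]
        c = bin_reads(reads, {"chr1": L}, 100)
        mc = bin_reads(mirrored, {"chr1": L}, 100)
        for q in (1, 4):
            a = profile_sample(c, genes, q)
            b = profile_sample(mc, mgenes, q)
            np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_tss_profile_flat_on_uniform_coverage(self):
        counts = _uniform_counts()
        genes = [_gene(f"g{i}", start=5000 + i * 8000, end=7000 + i * 8000,
                       strand="-" if i % 2 else "+", expr=float(i + 1))
                 for i in range(4)]
        expected = 5 / (counts.library_size / 1e6) / 0.1
        prof = tss_profile(counts, genes, 2)
        assert len(prof.values) == 40
        np.testing.assert_allclose(prof.values, expected)


class TestRatioProfile:
    def test_identical_profiles_give_flat_one(self):
        v = np.abs(np.random.default_rng(1).normal(5, 1, 150)) + 1
        np.testing.assert_allclose(ratio_profile(v, v), np.ones(150))

    def test_zero_control_after_flooring_is_error(self):
        with pytest.raises(ValueError, match="zero"):
            ratio_profile(np.ones(150), np.zeros(150))

    def test_floor_rescues_zero_control(self):
        out = ratio_profile(np.ones(150), np.zeros(150), floor=0.5)
        np.testing.assert_allclose(out, 2.0)
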