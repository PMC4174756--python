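import filecmp
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from chipctrl.binning import bin_reads
from chipctrl.sim import (SimConfig, build_densities, expression_counts,
                          sample_reads, write_dataset)

from conftest import small_sim_config


class TestDensities:
    def test_each_density_integrates_to_one(self):
        tracks = build_densities(small_sim_config())
        for kind, track in tracks.densities.items():
            total = sum(float(v.sum()) for v in track.values())
            assert total == pytest.approx(1.0), kind

    def test_histone_free_chrm_analog(self):
        tracks = build_densities(small_sim_config())
        assert tracks.densities["H3"]["chrM"].sum() == 0.0
        assert tracks.densities["H3K27me3"]["chrM"].sum() == 0.0
        assert tracks.densities["WCE"]["chrM"].sum() > 0.0

    def test_degenerate_config_gives_uniform_h3(self):
        cfg = small_sim_config()
        cfg.tss_dip_depth = 0.0
        cfg.body_boost = 0.0
        cfg.n_hotspots = 0
        tracks = build_densities(cfg)
        h3 = tracks.densities["H3"]["chr1"]
        np.testing.assert_allclose(h3, h3[0])

    def test_modification_fraction_decreases_with_expression(self):
        tracks = build_densities(small_sim_config())
        genes = sorted(tracks.genes, key=lambda g: g.expression_rpkm)
        m = [tracks.modification[g.gene_id] for g in genes]
        # logistic in log expression: monotone non-increasing over the rank order
        assert all(a >= b - 1e-12 for a, b in zip(m, m[1:]))

    def test_invalid_config_rejected(self):
        cfg = small_sim_config()
        cfg.n_genes = 0
        with pytest.raises(ValueError):
            build_densities(cfg)


class TestSampleReads:
    def test_same_seed_gives_identical_reads(self):
        tracks = build_densities(small_sim_config())
        a = sample_reads(tracks, "WCE", 2000, seed=5)
        b = sample_reads(tracks, "WCE", 2000, seed=5)
        assert a == b

    def test_mapq_filter_retains_configured_fraction(self):
        tracks = build_densities(small_sim_config())
        reads = sample_reads(tracks, "H3_rep1", 20_000)
        kept = sum(1 for r in reads if r.mapq >= 20) / len(reads)
        assert kept == pytest.approx(0.9, abs=0.02)

    def test_reads_fit_their_contigs(self):
        cfg = small_sim_config()
        tracks = build_densities(cfg)
        for r in sample_reads(tracks, "WCE", 5000):
            assert 0 <= r.start < r.end <= cfg.contigs[r.contig]
            assert r.end - r.start == cfg.fragment_length

    def test_uniform_density_counts_are_poisson(self):
        # degenerate flat genome: per-bin counts must pass a Poisson GOF
        cfg = small_sim_config()
        cfg.tss_dip_depth = cfg.body_boost = cfg.wce_tss_peak = 0.0
        cfg.n_hotspots = 0
        cfg.wce_chrm_factor = 1.0
        cfg.mapq_below_fraction = 0.0
        tracks = build_densities(cfg)
        n = 100_000
        reads = sample_reads(tracks, "WCE", n, seed=2)
        binned = bin_reads(reads, cfg.contigs, 1000, "u")
        counts = binned.flat()
        lam = n / counts.size
        kmax = int(stats.poisson.ppf(0.999, lam))
        observed = np.bincount(np.minimum(counts, kmax + 1), minlength=kmax + 2)
        pmf = stats.poisson.pmf(np.arange(kmax + 1), lam)
        expected = np.append(pmf, 1 - pmf.sum()) * counts.size
        keep = expected >= 5
        p = stats.chisquare(observed[keep], expected[keep] * observed[keep].sum()
                            / expected[keep].sum()).pvalue
        assert p > 0.01


class TestWriteDataset:
    def test_manifest_and_files(self, tmp_path):
        cfg = small_sim_config()
        manifest = write_dataset(cfg, tmp_path / "d")
        assert set(manifest["samples"]) == set(cfg.library_sizes)
        for fname in manifest["samples"].values():
            assert (tmp_path / "d" / fname).exists()
        for fname in manifest["annotation"].values():
            assert (tmp_path / "d" / fname).exists()

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = small_sim_config()
        write_dataset(cfg, tmp_path / "a")
        write_dataset(cfg, tmp_path / "b")
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(tmp_path / "a", tmp_path / "b",
                                                   files, shallow=False)
        assert mismatch == [] and errors == []

    def test_expression_counts_scale_with_rpkm(self):
        tracks = build_densities(small_sim_config())
        counts = expression_counts(tracks)
        genes = sorted(tracks.genes, key=lambda g: g.expression_rpkm)
        lo = np.mean([counts[g.gene_id] for g in genes[:10]])
        hi = np.mean([counts[g.gene_id] for g in genes[-10:]])
        assert hi > lo
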