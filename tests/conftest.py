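import numpy as np
import pytest

from chipctrl import enrichment
from chipctrl.binning import bin_reads
from chipctrl.io_formats import DEFAULT_MAPQ_MIN
from chipctrl.sim import (SimConfig, build_densities, expression_counts,
                          sample_reads, sample_kind)


def small_sim_config(seed: int = 11) -> SimConfig:
    """A reduced study: one 1 Mb contig + chrM analog, 50 genes, ~3e4 reads."""
    return SimConfig(
        seed=seed,
        contigs={"chr1": 1_000_000, "chrM": 10_000},
        n_genes=50,
        gene_length_log_mean=float(np.log(3000.0)),
        gene_length_log_sd=0.3,
        gene_length_min=1000,
        gene_length_max=8000,
        library_sizes={"WCE": 40_000, "H3_rep1": 30_000, "H3K27me3_rep1": 35_000},
    )


class Study:
    """The default desk-scale simulated study, processed once per session.

    Reads are MAPQ-filtered and replicates merged per sample kind; genes
    carry expression RPKM recomputed from the simulated count table the way
    the pipeline does.
    """

    def __init__(self, config: SimConfig):
        self.config = config
        self.tracks = build_densities(config)
        self.reads: dict[str, list] = {}
        for sample, n in config.library_sizes.items():
            kept = [r for r in sample_reads(self.tracks, sample, n)
                    if r.mapq >= DEFAULT_MAPQ_MIN]
            self.reads.setdefault(sample_kind(sample), []).extend(kept)
        counts = expression_counts(self.tracks)
        genes = [g for g in self.tracks.genes]
        rpkm = enrichment.expression_rpkm(
            np.array([counts[g.gene_id] for g in genes], dtype=float),
            np.array([g.exon_length for g in genes], dtype=float),
            config.rna_library_size)
        for g, v in zip(genes, rpkm):
            g.expression_rpkm = float(v)
        self.genes = genes
        self.bins1k = {k: bin_reads(r, config.contigs, 1000, k)
                       for k, r in self.reads.items()}
        self.bins100 = {k: bin_reads(r, config.contigs, 100, k)
                        for k, r in self.reads.items()}


@pytest.fixture(scope="session")
def study() -> Study:
    return Study(SimConfig(seed=123))
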