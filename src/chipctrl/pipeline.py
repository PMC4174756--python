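"""End-to-end control-comparison report.

Chains the stages of the analysis in the order the study walks through them:

1. 1 kb count distributions of the controls, depth-matched by binomial
   thinning, against the Poisson reference;
2. differential screen WCE vs H3 over 1 kb bins and over genes;
3. peak-set concordance (when external peak calls are provided);
4. expression-quartile metagene and TSS profiles plus mark/control ratio
   profiles;
5. enrichment-expression correlation summary (mark, controls, ratios, for
   gene body and promoter).

Every output is a TSV with a header row; a manifest records the seed, a
config hash and the files written. Reruns with the same config and seed
produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binning, enrichment, metagene, peakcmp, resample
from .io_formats import (GeneModel, read_bed_reads, read_chrom_sizes,
                         read_expression_table, read_gene_table, read_peaks)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Paths and thresholds for one report run.

    ``reads`` maps a sample group (e.g. "WCE", "H3", "H3K27me3") to the BED
    files of its replicates; replicates are merged before analysis, as the
    study does for profiling and peak calling.
    """

    reads: dict[str, list[str]]
    genes: str
    chrom_sizes: str
    expression: str
    rna_library_size: int | None = None  # default: total of the count table
    peaks_a: str | None = None
    peaks_b: str | None = None
    peak_score_column: str = "score"
    mark: str = "H3K27me3"
    controls: list[str] = field(default_factory=lambda: ["WCE", "H3"])
    seed: int = 0
    mapq_min: int = 20
    fdr_threshold: float = 0.05
    promoter_width: int = 4000
    rpkm_exclude: float = 100.0
    downsample_distributions: bool = True
    tss_window: int = 2000
    tss_step: int = 100

    def validate(self) -> None:
        if self.fdr_threshold <= 0 or self.promoter_width <= 0 or self.rpkm_exclude <= 0:
            raise ValueError("thresholds must be positive")
        for group in (self.mark, *self.controls):
            if group not in self.reads:
                raise ValueError(f"no read files configured for group {group!r}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @classmethod
    def from_sim_dir(cls, data_dir: str | Path, **overrides) -> "RunConfig":
        """Build a config from a simulated dataset directory (manifest.yaml)."""
        data_dir = Path(data_dir)
        with open(data_dir / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        groups: dict[str, list[str]] = {}
        for sample, fname in sorted(manifest["samples"].items()):
            kind = sample.split("_rep")[0]
            groups.setdefault(kind, []).append(str(data_dir / fname))
        ann = manifest["annotation"]
        cfg = cls(reads=groups,
                  genes=str(data_dir / ann["genes"]),
                  chrom_sizes=str(data_dir / ann["chrom_sizes"]),
                  expression=str(data_dir / ann["expression"]),
                  rna_library_size=manifest.get("rna_library_size"),
                  seed=int(manifest.get("seed", 0)))
        for key, value in overrides.items():
            setattr(cfg, key, value)
        return cfg


def load_genes_with_expression(config: RunConfig) -> list[GeneModel]:
    """Gene models with expression RPKM computed from the count table.

    The RNA library size is taken from the config when known (the mapped
    total of the RNA-seq library); the count-table total is only a fallback,
    appropriate when the table covers the whole transcriptome.
    """
    genes = read_gene_table(config.genes)
    counts = read_expression_table(config.expression)
    missing = [g.gene_id for g in genes if g.gene_id not in counts]
    if missing:
        raise ValueError(f"expression table missing {len(missing)} genes "
                         f"(first: {missing[:3]})")
    library = config.rna_library_size or sum(counts.values())
    if library <= 0:
        raise ValueError("expression table has zero total count")
    vec = enrichment.expression_rpkm(
        np.array([counts[g.gene_id] for g in genes], dtype=float),
        np.array([g.exon_length for g in genes], dtype=float),
        int(library))
    for g, rpkm in zip(genes, vec):
        g.expression_rpkm = float(rpkm)
    return genes


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle into ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    contig_lengths = read_chrom_sizes(config.chrom_sizes)
    genes = load_genes_with_expression(config)

    group_reads = {}
    for group, paths in config.reads.items():
        merged = []
        for p in paths:
            merged.extend(read_bed_reads(p, config.mapq_min))
        group_reads[group] = merged
        logger.info("group %s: %d reads after MAPQ filter (%d files)",
                    group, len(merged), len(paths))

    bins1k = {g: binning.bin_reads(r, contig_lengths, 1000, g)
              for g, r in group_reads.items()}
    bins100 = {g: binning.bin_reads(r, contig_lengths, 100, g)
               for g, r in group_reads.items()}

    # --- stage 1: count distributions at matched depth + Poisson reference
    dist_samples = [bins1k[g] for g in config.controls + [config.mark]]
    if config.downsample_distributions:
        dist_samples = resample.downsample_to_min(dist_samples, config.seed)
    null = resample.poisson_null(dist_samples, seed=config.seed)
    dist_rows = []
    for s in list(dist_samples) + [null]:
        d = enrichment.count_distribution(s, normalize=True)
        d.insert(0, "sample", s.sample_name)
        dist_rows.append(d)
    _write(pd.concat(dist_rows, ignore_index=True), outdir / "distribution.tsv")
    outputs.append("distribution.tsv")

    # --- stage 2: differential screen between the two controls
    ctrl_a, ctrl_b = config.controls[0], config.controls[1]
    ma_bins = enrichment.differential_screen_bins(
        bins1k[ctrl_a], bins1k[ctrl_b], config.fdr_threshold)
    _write(ma_bins, outdir / "ma_bins.tsv")
    outputs.append("ma_bins.tsv")

    gene_intervals = [(g.contig, g.start, g.end) for g in genes]
    gene_ids = [g.gene_id for g in genes]
    xg = enrichment.count_read_centers(group_reads[ctrl_a], gene_intervals)
    yg = enrichment.count_read_centers(group_reads[ctrl_b], gene_intervals)
    ma_genes = enrichment.differential_screen(
        xg, yg, len(group_reads[ctrl_a]), len(group_reads[ctrl_b]),
        gene_ids, config.fdr_threshold)
    _write(ma_genes, outdir / "ma_genes.tsv")
    outputs.append("ma_genes.tsv")

    # --- stage 3: peak concordance (optional)
    if config.peaks_a and config.peaks_b:
        peaks_a = read_peaks(config.peaks_a, ctrl_a, config.peak_score_column)
        peaks_b = read_peaks(config.peaks_b, ctrl_b, config.peak_score_column)
        result = peakcmp.overlap_peaks(peaks_a, peaks_b)
        summary = pd.DataFrame([peakcmp.concordance_summary(result)])
        _write(summary, outdir / "peaks_summary.tsv")
        _write(peakcmp.score_distributions(result), outdir / "peaks_scores.tsv")
        pairs = pd.DataFrame(
            [{"contig": a.contig, "start_a": a.start, "end_a": a.end,
              "score_a": a.score, "start_b": b.start, "end_b": b.end,
              "score_b": b.score, "shared_bp": s}
             for a, b, s in result.pairs])
        _write(pairs, outdir / "peaks_pairs.tsv")
        outputs += ["peaks_summary.tsv", "peaks_scores.tsv", "peaks_pairs.tsv"]
        peaks_status = "done"
    else:
        peaks_status = "skipped (no peak files configured)"
        logger.info("peak concordance skipped: no peak files")

    # --- stage 4: metagene / TSS / ratio profiles
    profile_rows, tss_rows = [], []
    profiles: dict[tuple[str, int], metagene.MetageneProfile] = {}
    tss_profiles: dict[tuple[str, int], metagene.TSSProfile] = {}
    for group in config.controls + [config.mark]:
        for q in (1, 2, 3, 4):
            prof = metagene.profile_sample(bins100[group], genes, q,
                                           config.rpkm_exclude)
            profiles[(group, q)] = prof
            smoothed = metagene.smooth_profile(prof.values)
            profile_rows += [{"sample": group, "quartile": q, "position": i - 50,
                              "value": v, "n_genes": prof.n_genes}
                             for i, v in enumerate(smoothed)]
            tprof = metagene.tss_profile(bins100[group], genes, q,
                                         config.tss_window, config.tss_step,
                                         config.rpkm_exclude)
            tss_profiles[(group, q)] = tprof
            tsm = metagene.smooth_profile(tprof.values)
            tss_rows += [{"sample": group, "quartile": q, "offset": int(o),
                          "value": v, "n_genes": tprof.n_genes}
                         for o, v in zip(tprof.offsets, tsm)]
    for control in config.controls:
        for q in (1, 2, 3, 4):
            ratio = metagene.ratio_profile(profiles[(config.mark, q)],
                                           profiles[(control, q)])
            profile_rows += [{"sample": f"{config.mark}/{control}", "quartile": q,
                              "position": i - 50, "value": v,
                              "n_genes": profiles[(config.mark, q)].n_genes}
                             for i, v in enumerate(ratio)]
            tratio = metagene.ratio_profile(tss_profiles[(config.mark, q)],
                                            tss_profiles[(control, q)])
            tss_rows += [{"sample": f"{config.mark}/{control}", "quartile": q,
                          "offset": int(o), "value": v,
                          "n_genes": tss_profiles[(config.mark, q)].n_genes}
                         for o, v in zip(tss_profiles[(config.mark, q)].offsets, tratio)]
    _write(pd.DataFrame(profile_rows), outdir / "profiles_gene.tsv")
    _write(pd.DataFrame(tss_rows), outdir / "profiles_tss.tsv")
    outputs += ["profiles_gene.tsv", "profiles_tss.tsv"]

    # --- stage 5: enrichment table and correlation summary
    table = enrichment.build_enrichment_table(
        genes, group_reads, contig_lengths, config.promoter_width)
    _write(table.reset_index(), outdir / "enrichment_table.tsv")
    corr = enrichment.correlation_summary(table, config.mark, config.controls)
    _write(corr, outdir / "correlations.tsv")
    outputs += ["enrichment_table.tsv", "correlations.tsv"]

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "reads_kept": {g: len(r) for g, r in group_reads.items()},
        "n_genes": len(genes),
        "peak_concordance": peaks_status,
        "outputs": outputs,
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
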