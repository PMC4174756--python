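"""Synthetic ChIP-seq dataset generator.

Emits read sets (one WCE, two H3 replicates, three H3K27me3 replicates —
a typical design for this comparison), gene annotations, expression counts and
truth tracks, with the statistical structure the analysis assumes:

* library-size differences across samples (WCE deepest);
* a histone-free mitochondrial analog contig ("chrM"): zero H3/H3K27me3
  density, several-fold WCE enrichment;
* shared repeat-like hotspot bins enriched in every sample;
* nucleosome occupancy with a TSS dip whose depth and width grow with
  expression, and a gene-body elevation for expressed genes (so both
  controls are somewhat enriched over highly expressed genes);
* a WCE-specific TSS peak growing with expression (nucleosome-free region
  over-represented in sheared extract);
* an H3K27me3 modification fraction per gene, logistic and decreasing in
  log-expression, spread over smoothly decaying gene domains, so mark
  density = occupancy x modification fraction.

Densities are piecewise-constant at 10 bp resolution; fragment midpoints are
drawn by inverse-CDF from the normalized density, reads are fixed-length
intervals around midpoints with random strand, and a configured fraction of
reads receives MAPQ below 20 to exercise the filter.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._rng import child_rng
from .io_formats import (GeneModel, Peak, ReadRecord, write_bed_reads,
                         write_chrom_sizes, write_gene_table, write_peaks)

logger = logging.getLogger(__name__)


def _default_contigs() -> dict[str, int]:
    return {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000, "chrM": 20_000}


def _default_libraries() -> dict[str, int]:
    # WCE deepest, H3 intermediate, H3K27me3 replicates similar — the depth
    # ordering such experiments typically show, at desk scale.
    return {
        "WCE": 240_000,
        "H3_rep1": 150_000,
        "H3_rep2": 160_000,
        "H3K27me3_rep1": 180_000,
        "H3K27me3_rep2": 190_000,
        "H3K27me3_rep3": 200_000,
    }


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the desk-scale study conditions."""

    seed: int = 0
    contigs: dict[str, int] = field(default_factory=_default_contigs)
    chrm: str = "chrM"
    n_genes: int = 300
    gene_length_log_mean: float = math.log(5000.0)
    gene_length_log_sd: float = 0.4
    gene_length_min: int = 1500
    gene_length_max: int = 20000
    expression_log_mean: float = math.log(5.0)
    expression_log_sd: float = 1.5
    fragment_length: int = 200
    library_sizes: dict[str, int] = field(default_factory=_default_libraries)
    resolution: int = 10
    # occupancy model
    tss_dip_depth: float = 0.8        # depth at the top expression rank
    tss_dip_width_min: float = 100.0  # Gaussian sigma, lowest rank
    tss_dip_width_max: float = 250.0  # Gaussian sigma, highest rank
    body_boost: float = 0.5           # gene-body elevation at top rank (both controls)
    # WCE-specific structure
    wce_tss_peak: float = 3.0
    wce_tss_peak_width: float = 150.0
    wce_chrm_factor: float = 8.0
    # shared repeat-like hotspots
    n_hotspots: int = 30
    hotspot_width: int = 1000
    hotspot_intensity: float = 9.0    # added on top of the unit baseline
    # modification model (H3K27me3)
    mod_background: float = 0.15
    mod_min: float = 0.05
    mod_max: float = 0.8
    mod_slope: float = -1.0           # logistic slope in log-expression
    mod_decay_bp: float = 3000.0      # Gaussian decay of gene domains outside the body
    # read-level nuisance
    mapq_below_fraction: float = 0.1
    # expression read counts
    rna_library_size: int = 1_000_000
    exon_fraction: float = 0.5

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be > 0")
        if not self.contigs or self.chrm not in self.contigs:
            raise ValueError("contigs must include the chrM analog")
        if min(self.library_sizes.values()) <= 0:
            raise ValueError("library sizes must be > 0")
        for name, val in (("tss_dip_depth", self.tss_dip_depth),
                          ("mod_background", self.mod_background),
                          ("mod_min", self.mod_min), ("mod_max", self.mod_max),
                          ("mapq_below_fraction", self.mapq_below_fraction)):
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def sample_kind(sample_name: str) -> str:
    """'H3_rep2' -> 'H3'; replicates of a kind share a density track."""
    return sample_name.split("_rep")[0]


@dataclass
class TruthTracks:
    """Normalized expected-density tracks plus the latent truth behind them."""

    config: SimConfig
    genes: list[GeneModel]                       # expression_rpkm filled in
    modification: dict[str, float]               # gene_id -> m_g
    dip_depth: dict[str, float]                  # gene_id -> delta_g
    hotspots: list[tuple[str, int, int]]
    densities: dict[str, dict[str, np.ndarray]]  # kind -> contig -> cell mass

    def cell_edges(self, contig: str) -> np.ndarray:
        res = self.config.resolution
        n = -(-self.config.contigs[contig] // res)
        return np.arange(n + 1) * res


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    """Random non-overlapping gene placement with a one-gene-width margin.

    The margin keeps every gene's +/- one-width profile window on its contig
    and keeps neighboring modification domains from piling up at the TSS.
    Genes are laid out sequentially per contig — minimal required spacing
    plus randomly distributed slack — so placement succeeds whenever the
    genome can hold the genes at all, at any crowding level.
    """
    contigs = [c for c in config.contigs if c != config.chrm]
    lengths = np.exp(rng.normal(config.gene_length_log_mean,
                                config.gene_length_log_sd, config.n_genes))
    lengths = np.clip(lengths, config.gene_length_min, config.gene_length_max).astype(int)
    expression = np.exp(rng.normal(config.expression_log_mean,
                                   config.expression_log_sd, config.n_genes))

    # assign genes to contigs, tracking each contig's committed footprint:
    # leading margin + bodies + between-gene gaps of max(w_i, w_{i+1}) +
    # trailing margin
    caps = {c: config.contigs[c] for c in contigs}
    req = {c: 0 for c in contigs}
    assigned: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    for i in rng.permutation(config.n_genes):
        w = int(lengths[i])
        placed = False
        for ci in rng.permutation(len(contigs)):
            c = contigs[ci]
            prev = assigned[c][-1][1] if assigned[c] else None
            new_req = (3 * w if prev is None
                       else req[c] - prev + max(prev, w) + 2 * w)
            if new_req <= caps[c]:
                assigned[c].append((int(i), w))
                req[c] = new_req
                placed = True
                break
        if not placed:
            raise ValueError(
                f"genome too small for n_genes={config.n_genes} at the "
                f"configured gene-length distribution")

    genes: list[GeneModel] = []
    for c in contigs:
        entries = assigned[c]
        if not entries:
            continue
        slack = caps[c] - req[c]
        if slack > 0:
            cuts = np.sort(rng.integers(0, slack + 1, size=len(entries)))
            extras = np.diff(np.concatenate([[0], cuts]))
        else:
            extras = np.zeros(len(entries), dtype=int)
        pos = 0
        for j, (i, w) in enumerate(entries):
            lead = w if j == 0 else max(entries[j - 1][1], w)
            pos += lead + int(extras[j])
            strand = "+" if rng.random() < 0.5 else "-"
            exon_length = max(1, int(round(config.exon_fraction * w)))
            genes.append(GeneModel(f"gene{i:04d}", c, pos, pos + w, strand,
                                   exon_length, float(expression[i])))
            pos += w
    genes.sort(key=lambda g: (g.contig, g.start))
    return genes


def _expression_rank(genes: list[GeneModel]) -> dict[str, float]:
    """Rank quantile in [0, 1], 0 = least expressed."""
    ordered = sorted(genes, key=lambda g: (g.expression_rpkm, g.gene_id))
    n = len(ordered)
    return {g.gene_id: (i / (n - 1) if n > 1 else 0.5) for i, g in enumerate(ordered)}


def build_densities(config: SimConfig) -> TruthTracks:
    """Construct normalized expected-density tracks for WCE, H3 and H3K27me3."""
    config.validate()
    rng = child_rng(config.seed, "sim", "layout")
    genes = _place_genes(config, rng)
    rank = _expression_rank(genes)
    res = config.resolution
    ncells = {c: -(-length // res) for c, length in config.contigs.items()}
    centers = {c: (np.arange(n) + 0.5) * res for c, n in ncells.items()}

    # hotspots: repeat-like bins enriched in every sample, never on chrM
    hotspots: list[tuple[str, int, int]] = []
    hot_contigs = [c for c in config.contigs if c != config.chrm]
    for _ in range(config.n_hotspots):
        contig = hot_contigs[rng.integers(len(hot_contigs))]
        start = int(rng.integers(0, config.contigs[contig] - config.hotspot_width))
        hotspots.append((contig, start, start + config.hotspot_width))

    hot_track = {c: np.zeros(n) for c, n in ncells.items()}
    for contig, start, end in hotspots:
        hot_track[contig][start // res: -(-end // res)] += config.hotspot_intensity

    boost_track = {c: np.zeros(n) for c, n in ncells.items()}
    dip_factor = {c: np.ones(n) for c, n in ncells.items()}
    wce_peak_track = {c: np.zeros(n) for c, n in ncells.items()}
    mod_track = {c: np.full(n, config.mod_background) for c, n in ncells.items()}

    log_expr = np.log([g.expression_rpkm for g in genes])
    e0 = float(np.median(log_expr))
    modification: dict[str, float] = {}
    dip_depth: dict[str, float] = {}
    for g in genes:
        q = rank[g.gene_id]
        x = centers[g.contig]
        body = slice(g.start // res, -(-g.end // res))
        boost_track[g.contig][body] += config.body_boost * q

        delta = config.tss_dip_depth * q
        sigma = config.tss_dip_width_min + (config.tss_dip_width_max
                                            - config.tss_dip_width_min) * q
        dip_depth[g.gene_id] = delta
        lo = max(0, int((g.tss - 5 * sigma) // res))
        hi = min(ncells[g.contig], int(-(-(g.tss + 5 * sigma) // res)))
        window = slice(lo, hi)
        dip_factor[g.contig][window] *= (
            1.0 - delta * np.exp(-0.5 * ((x[window] - g.tss) / sigma) ** 2))

        psig = config.wce_tss_peak_width
        lo = max(0, int((g.tss - 5 * psig) // res))
        hi = min(ncells[g.contig], int(-(-(g.tss + 5 * psig) // res)))
        window = slice(lo, hi)
        wce_peak_track[g.contig][window] += (
            config.wce_tss_peak * q * np.exp(-0.5 * ((x[window] - g.tss) / psig) ** 2))

        # logistic modification fraction, decreasing in log expression
        z = config.mod_slope * (math.log(g.expression_rpkm) - e0)
        m_g = config.mod_min + (config.mod_max - config.mod_min) / (1.0 + math.exp(-z))
        modification[g.gene_id] = m_g
        # smooth domain: 1 inside the body, Gaussian decay outside
        sig_out = config.mod_decay_bp
        lo = max(0, int((g.start - 4 * sig_out) // res))
        hi = min(ncells[g.contig], int(-(-(g.end + 4 * sig_out) // res)))
        window = slice(lo, hi)
        xx = x[window]
        dist = np.maximum(0.0, np.maximum(g.start - xx, xx - g.end))
        s = np.exp(-0.5 * (dist / sig_out) ** 2)
        mod_track[g.contig][window] += (m_g - config.mod_background) * s
    for c in mod_track:
        np.clip(mod_track[c], 0.0, 1.0, out=mod_track[c])

    occupancy = {}
    wce = {}
    k27 = {}
    for c, n in ncells.items():
        if c == config.chrm:
            occupancy[c] = np.zeros(n)
            wce[c] = np.full(n, config.wce_chrm_factor)
            k27[c] = np.zeros(n)
        else:
            occupancy[c] = (1.0 + boost_track[c] + hot_track[c]) * dip_factor[c]
            wce[c] = 1.0 + boost_track[c] + hot_track[c] + wce_peak_track[c]
            k27[c] = occupancy[c] * mod_track[c]

    densities = {}
    for kind, track in (("WCE", wce), ("H3", occupancy), ("H3K27me3", k27)):
        total = sum(float(v.sum()) for v in track.values())
        if total <= 0:
            raise ValueError(f"{kind}: density integrates to zero")
        densities[kind] = {c: v / total for c, v in track.items()}

    return TruthTracks(config, genes, modification, dip_depth, hotspots, densities)


def sample_reads(tracks: TruthTracks, sample_name: str, n_reads: int,
                 seed: int | np.random.Generator | None = None) -> list[ReadRecord]:
    """Draw reads for one library by inverse-CDF over the density cells.

    Fragment midpoints are i.i.d. from the sample kind's density; reads are
    fixed-length intervals centered on midpoints with uniform strand.
    Midpoints whose fragment would extend past the contig are redrawn.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    config = tracks.config
    kind = sample_kind(sample_name)
    if kind not in tracks.densities:
        raise ValueError(f"unknown sample kind {kind!r}")
    if seed is None or isinstance(seed, int):
        rng = child_rng(config.seed if seed is None else seed, "sim", "reads", sample_name)
    else:
        rng = seed
    res = config.resolution
    contigs = list(config.contigs)
    cell_counts = [len(tracks.densities[kind][c]) for c in contigs]
    mass = np.concatenate([tracks.densities[kind][c] for c in contigs])
    cum = np.cumsum(mass)
    cum /= cum[-1]
    bounds = np.cumsum([0] + cell_counts)
    flen = config.fragment_length
    half = flen // 2

    mids = np.empty(n_reads, dtype=np.int64)
    which = np.empty(n_reads, dtype=np.int64)
    todo = np.arange(n_reads)
    while len(todo):
        u = rng.random(len(todo))
        cell = np.searchsorted(cum, u, side="right")
        ci = np.searchsorted(bounds, cell, side="right") - 1
        local = cell - bounds[ci]
        pos = local * res + rng.integers(0, res, size=len(todo))
        clen = np.array([config.contigs[contigs[i]] for i in ci])
        ok = (pos - half >= 0) & (pos - half + flen <= clen) & (pos < clen)
        mids[todo[ok]] = pos[ok]
        which[todo[ok]] = ci[ok]
        todo = todo[~ok]

    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")
    low = rng.random(n_reads) < config.mapq_below_fraction
    mapq = np.where(low, rng.integers(0, 20, size=n_reads),
                    rng.integers(20, 61, size=n_reads))
    reads = [ReadRecord(contigs[int(which[i])], int(mids[i] - half),
                        int(mids[i] - half + flen), str(strands[i]), int(mapq[i]))
             for i in range(n_reads)]
    return reads


def expression_counts(tracks: TruthTracks,
                      seed: int | np.random.Generator | None = None) -> dict[str, int]:
    """Per-gene RNA-seq read counts: Poisson around the expected RPKM.

    expected count = rpkm * (exon_length/1000) * (library/1e6); the RNA side
    is only used to rank genes, so count-level simulation suffices.
    """
    config = tracks.config
    if seed is None or isinstance(seed, int):
        rng = child_rng(config.seed if seed is None else seed, "sim", "expression")
    else:
        rng = seed
    counts = {}
    for g in tracks.genes:
        lam = g.expression_rpkm * (g.exon_length / 1000.0) * (config.rna_library_size / 1e6)
        counts[g.gene_id] = int(rng.poisson(lam))
    return counts


def write_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Write the full synthetic dataset; returns (and writes) the manifest.

    Files: one BED per library, genes.tsv, chrom.sizes, expression.tsv,
    truth_genes.tsv, truth_hotspots.tsv and manifest.yaml carrying the seed
    and a config hash. Byte-identical across reruns with the same config.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracks = build_densities(config)

    files: dict[str, str] = {}
    for sample, n_reads in config.library_sizes.items():
        reads = sample_reads(tracks, sample, n_reads)
        path = outdir / f"{sample}.bed"
        write_bed_reads(path, reads)
        files[sample] = path.name

    write_gene_table(outdir / "genes.tsv", tracks.genes)
    write_chrom_sizes(outdir / "chrom.sizes", config.contigs)
    counts = expression_counts(tracks)
    with open(outdir / "expression.tsv", "w") as fh:
        fh.write("gene_id\tcount\n")
        for g in tracks.genes:
            fh.write(f"{g.gene_id}\t{counts[g.gene_id]}\n")
    with open(outdir / "truth_genes.tsv", "w") as fh:
        fh.write("gene_id\texpression_rpkm\tmodification_fraction\ttss_dip_depth\n")
        for g in tracks.genes:
            fh.write(f"{g.gene_id}\t{g.expression_rpkm:.6g}"
                     f"\t{tracks.modification[g.gene_id]:.6g}"
                     f"\t{tracks.dip_depth[g.gene_id]:.6g}\n")
    with open(outdir / "truth_hotspots.tsv", "w") as fh:
        fh.write("contig\tstart\tend\n")
        for contig, start, end in tracks.hotspots:
            fh.write(f"{contig}\t{start}\t{end}\n")

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "rna_library_size": config.rna_library_size,
        "samples": files,
        "annotation": {"genes": "genes.tsv", "chrom_sizes": "chrom.sizes",
                       "expression": "expression.tsv"},
        "truth": {"genes": "truth_genes.tsv", "hotspots": "truth_hotspots.tsv"},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("wrote synthetic dataset to %s (%d samples, %d genes)",
                outdir, len(files), len(tracks.genes))
    return manifest


def simulate_peak_sets(n_shared: int = 500, n_only_a: int = 50, n_only_b: int = 50,
                       r_true: float = 0.9, seed: int = 0,
                       contig: str = "chr1", contig_length: int = 2_000_000,
                       peak_width: int = 400,
                       sample_a: str = "WCE", sample_b: str = "H3",
                       ) -> tuple[list[Peak], list[Peak]]:
    """Two synthetic peak sets with known concordance structure.

    Shared peaks occupy jittered versions of the same intervals (guaranteed
    >= 1 bp overlap) with bivariate-normal scores at correlation ``r_true``;
    set-unique peaks sit elsewhere with much lower scores, mirroring the
    observation that caller-unique peaks score low.
    """
    rng = child_rng(seed, "sim", "peaks")
    n_slots = n_shared + n_only_a + n_only_b
    gap = contig_length // (n_slots + 1)
    if gap <= 2 * peak_width:
        raise ValueError("contig too short for the requested peak count")
    slots = (np.arange(n_slots) + 1) * gap
    rng.shuffle(slots)
    shared_pos, a_pos, b_pos = (slots[:n_shared],
                                slots[n_shared:n_shared + n_only_a],
                                slots[n_shared + n_only_a:])
    cov = np.array([[1.0, r_true], [r_true, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_shared)
    base_scores = 150.0 + 40.0 * z
    set_a, set_b = [], []
    for i, pos in enumerate(shared_pos):
        jit = int(rng.integers(-peak_width // 4, peak_width // 4 + 1))
        set_a.append(Peak(contig, int(pos), int(pos) + peak_width,
                          float(np.clip(base_scores[i, 0], 1.0, None)), sample_a))
        set_b.append(Peak(contig, int(pos) + jit, int(pos) + jit + peak_width,
                          float(np.clip(base_scores[i, 1], 1.0, None)), sample_b))
    for pos in a_pos:
        set_a.append(Peak(contig, int(pos), int(pos) + peak_width,
                          float(np.clip(rng.normal(30.0, 8.0), 1.0, None)), sample_a))
    for pos in b_pos:
        set_b.append(Peak(contig, int(pos), int(pos) + peak_width,
                          float(np.clip(rng.normal(30.0, 8.0), 1.0, None)), sample_b))
    set_a.sort(key=lambda p: (p.contig, p.start, p.end))
    set_b.sort(key=lambda p: (p.contig, p.start, p.end))
    return set_a, set_b


def write_peak_fixture(path_a: str | Path, path_b: str | Path, **kwargs) -> None:
    """Write a synthetic concordant narrowPeak pair (see simulate_peak_sets)."""
    set_a, set_b = simulate_peak_sets(**kwargs)
    write_peaks(path_a, set_a)
    write_peaks(path_b, set_b)
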