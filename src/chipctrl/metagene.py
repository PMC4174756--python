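"""Average-coverage profiles over genes and around the TSS, by expression
quartile.

Each gene is assigned 150 bins of width 1/50 of the gene width, covering the
gene plus one gene width on either side (50 upstream + 50 body + 50
downstream); positions are strand-oriented so index 0 is the most upstream
and index 50 starts exactly at the TSS-side gene edge. A gene bin's coverage
is the unweighted mean RPKM of every 100 bp genome bin it overlaps by any
amount, positions are then averaged over the genes of an expression quartile,
and profiles are smoothed with a 3-bin running mean (truncated at the edges).
Genes with expression RPKM > 100 (ribosomal/mitochondrial-like outliers) are
excluded before quartiling so the linear-scale mean is not dominated by them.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .binning import BinnedCounts, bin_coverage_rpkm
from .io_formats import GeneModel

logger = logging.getLogger(__name__)

N_POSITIONS = 150
BODY_START = 50  # first gene-body position; the TSS sits at this bin's left edge
RPKM_EXCLUDE_DEFAULT = 100.0


@dataclass
class MetageneProfile:
    """150-position average RPKM profile for one sample and quartile."""

    sample_name: str
    quartile: int  # 1 = lowest expression .. 4 = highest
    values: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != N_POSITIONS:
            raise ValueError(f"profile must have {N_POSITIONS} positions")
        if self.n_genes <= 0:
            raise ValueError("profile averaged over zero genes")


@dataclass
class TSSProfile:
    """Fixed-bp profile around the TSS (default ±2000 bp in 100 bp steps).

    ``offsets`` are strand-oriented window start positions in bp relative to
    the TSS; the position count is even (no center bin straddles the TSS).
    """

    sample_name: str
    quartile: int
    offsets: np.ndarray
    values: np.ndarray
    n_genes: int


def gene_profile_bins(gene: GeneModel) -> np.ndarray:
    """The 150 half-open intervals tiling [start - w, end + w), strand-oriented.

    Returns an array of shape (150, 2) of float genomic edges; for − strand
    genes the rows are reversed so row 0 is the most upstream of the TSS.
    Bin edges are exact rationals of the gene width, so they are fractional
    whenever the width is not a multiple of 50.
    """
    w = gene.span
    if w < 50:
        raise ValueError(f"gene {gene.gene_id}: width {w} < 50 bp (bin width < 1 bp)")
    edges = gene.start - w + np.arange(N_POSITIONS + 1) * (w / 50.0)
    intervals = np.stack([edges[:-1], edges[1:]], axis=1)
    if gene.strand == "-":
        intervals = intervals[::-1]
    return intervals


def _interval_mean_rpkm(rpkm: np.ndarray, a: float, b: float, bin_width: int,
                        weighted: bool) -> float:
    """Mean RPKM of the genome bins overlapping [a, b) by any positive amount."""
    j0 = int(np.floor(a / bin_width + 1e-9))
    j1 = int(np.ceil(b / bin_width - 1e-9))
    j1 = max(j1, j0 + 1)
    window = rpkm[j0:j1]
    if not weighted:
        return float(window.mean())
    starts = np.arange(j0, j1) * bin_width
    overlap = np.minimum(starts + bin_width, b) - np.maximum(starts, a)
    return float(np.average(window, weights=overlap))


def gene_coverage_vector(rpkm_by_contig: dict[str, np.ndarray], gene: GeneModel,
                         bin_width: int, weighted: bool = False) -> np.ndarray | None:
    """Per-gene 150-position RPKM vector, or None if the window leaves the contig."""
    w = gene.span
    if w < 50:
        logger.warning("gene %s: width %d < 50 bp, excluded from profiling", gene.gene_id, w)
        return None
    rpkm = rpkm_by_contig.get(gene.contig)
    if rpkm is None:
        raise ValueError(f"gene {gene.gene_id} on unknown contig {gene.contig}")
    contig_len = len(rpkm) * bin_width
    if gene.start - w < 0 or gene.end + w > contig_len:
        logger.warning("gene %s: profile window off-contig, excluded", gene.gene_id)
        return None
    intervals = gene_profile_bins(gene)
    return np.array([_interval_mean_rpkm(rpkm, a, b, bin_width, weighted)
                     for a, b in intervals])


def exclude_extreme_genes(genes: list[GeneModel],
                          threshold: float = RPKM_EXCLUDE_DEFAULT) -> list[GeneModel]:
    """Drop genes with expression RPKM strictly above ``threshold``."""
    kept, removed = [], []
    for g in genes:
        if g.expression_rpkm is None:
            raise ValueError(f"gene {g.gene_id} has no expression_rpkm")
        (removed if g.expression_rpkm > threshold else kept).append(g.gene_id)
    if removed:
        logger.info("excluded %d genes with expression RPKM > %g: %s",
                    len(removed), threshold, ", ".join(removed[:10]))
    return [g for g in genes if g.gene_id in set(kept)]


def quartile_split(genes: list[GeneModel]) -> list[list[GeneModel]]:
    """Split genes into 4 expression groups, lowest (quartile 1) first.

    Stable sort by (expression, gene_id); when the count is not divisible by
    4 the extra genes go to the lowest quartiles.
    """
    if len(genes) < 4:
        raise ValueError(f"need >= 4 genes to form quartiles, got {len(genes)}")
    ordered = sorted(genes, key=lambda g: (g.expression_rpkm, g.gene_id))
    base, rem = divmod(len(ordered), 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    groups, at = [], 0
    for size in sizes:
        groups.append(ordered[at:at + size])
        at += size
    return groups


def profile_sample(counts: BinnedCounts, genes: list[GeneModel], quartile: int,
                   rpkm_exclude: float = RPKM_EXCLUDE_DEFAULT,
                   weighted: bool = False) -> MetageneProfile:
    """Metagene profile of one expression quartile (1 = lowest .. 4 = highest)."""
    if quartile not in (1, 2, 3, 4):
        raise ValueError(f"quartile must be 1..4, got {quartile}")
    group = quartile_split(exclude_extreme_genes(genes, rpkm_exclude))[quartile - 1]
    rpkm = bin_coverage_rpkm(counts)
    vectors = [v for g in group
               if (v := gene_coverage_vector(rpkm, g, counts.bin_width, weighted)) is not None]
    if not vectors:
        raise ValueError(f"quartile {quartile}: no genes left to profile after exclusions")
    return MetageneProfile(counts.sample_name, quartile,
                           np.mean(vectors, axis=0), len(vectors))


def metagene_profiles(counts: BinnedCounts, genes: list[GeneModel],
                      rpkm_exclude: float = RPKM_EXCLUDE_DEFAULT,
                      weighted: bool = False) -> list[MetageneProfile]:
    return [profile_sample(counts, genes, q, rpkm_exclude, weighted) for q in (1, 2, 3, 4)]


def tss_profile(counts: BinnedCounts, genes: list[GeneModel], quartile: int,
                window: int = 2000, step: int = 100,
                rpkm_exclude: float = RPKM_EXCLUDE_DEFAULT) -> TSSProfile:
    """Average RPKM in fixed-bp windows around the TSS, strand-oriented."""
    group = quartile_split(exclude_extreme_genes(genes, rpkm_exclude))[quartile - 1]
    rpkm = bin_coverage_rpkm(counts)
    offsets = np.arange(-window, window, step)
    vectors = []
    for g in group:
        vec = rpkm.get(g.contig)
        if vec is None:
            raise ValueError(f"gene {g.gene_id} on unknown contig {g.contig}")
        contig_len = len(vec) * counts.bin_width
        tss = g.tss
        if tss - window < 0 or tss + window + 1 > contig_len:
            logger.warning("gene %s: TSS window off-contig, excluded", g.gene_id)
            continue
        vals = np.empty(len(offsets))
        for i, k in enumerate(offsets):
            if g.strand == "+":
                a, b = tss + k, tss + k + step
            else:
                a, b = tss - k - step + 1, tss - k + 1
            vals[i] = _interval_mean_rpkm(vec, a, b, counts.bin_width, weighted=False)
        vectors.append(vals)
    if not vectors:
        raise ValueError(f"quartile {quartile}: no genes with a full TSS window")
    return TSSProfile(counts.sample_name, quartile, offsets,
                      np.mean(vectors, axis=0), len(vectors))


def smooth_profile(values: np.ndarray) -> np.ndarray:
    """3-bin running mean; at the two ends the mean is over the 2 existing bins."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        return v.copy()
    if len(v) == 1:
        return v.copy()
    padded = np.concatenate([[0.0], v, [0.0]])
    sums = padded[:-2] + padded[1:-1] + padded[2:]
    counts = np.full(len(v), 3.0)
    counts[0] = counts[-1] = 2.0
    return sums / counts


#: Windows spanning the full TSS dip support (~±0.1 gene width) against
#: wider flanks; used when assessing ratio-profile flatness, where averaging
#: over the whole dip region suppresses counting noise. The narrow
#: tss_dip_depth defaults suit localizing a sharp dip.
DIP_SUPPORT_CENTER = (45, 56)
DIP_SUPPORT_FLANKS = ((35, 45), (56, 66))


def tss_dip_depth(values: np.ndarray,
                  center: tuple[int, int] = (49, 52),
                  flanks: tuple[tuple[int, int], ...] = ((40, 47), (54, 61))) -> float:
    """Relative TSS dip depth of a 150-position profile.

    ``1 - mean(center)/mean(flanks)``: positive for a dip, negative for a
    peak, ~0 for a flat profile. The defaults straddle position 50 (the TSS)
    against nearby gene-edge flanks; window means rather than single
    positions keep the estimate stable against counting noise.
    """
    v = np.asarray(values, dtype=float)
    center_mean = v[center[0]:center[1]].mean()
    flank_mean = np.concatenate([v[a:b] for a, b in flanks]).mean()
    if flank_mean == 0:
        raise ValueError("flat-zero profile has no defined dip depth")
    return 1.0 - center_mean / flank_mean


def ratio_profile(mark, control, floor: float = 0.0) -> np.ndarray:
    """Position-wise mark/control ratio of smoothed profiles.

    Accepts MetageneProfile/TSSProfile objects (must agree on quartile and
    length) or bare arrays. Control positions are floored at ``floor``; any
    control position that is 0 after flooring is an error.
    """
    mv = mark.values if hasattr(mark, "values") else np.asarray(mark, dtype=float)
    cv = control.values if hasattr(control, "values") else np.asarray(control, dtype=float)
    if hasattr(mark, "quartile") and hasattr(control, "quartile"):
        if mark.quartile != control.quartile:
            raise ValueError("mark and control profiles are from different quartiles")
    if len(mv) != len(cv):
        raise ValueError("mark and control profiles differ in length")
    ms, cs = smooth_profile(mv), smooth_profile(cv)
    cs = np.maximum(cs, floor)
    if np.any(cs == 0):
        raise ValueError("control profile has zero positions after flooring")
    return ms / cs
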