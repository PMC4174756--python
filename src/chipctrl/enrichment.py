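"""Count distributions, differential screening, RPKM enrichment and
enrichment-expression correlation.

Two pseudocount conventions are used deliberately and must not be mixed:

* expression RPKM adds one count per million reads *before* dividing by exon
  length: ``rpkm = (cpm + 1) / (exon_length/1000)``;
* ChIP enrichment RPKM is computed over the full gene span (introns
  included) and adds 0.5 to the RPKM itself:
  ``rpkm = cpm / (span/1000) + 0.5``, which evens out background levels
  between samples of different depth.

The differential screen between two unreplicated samples is a two-sided
exact conditional binomial test: given the total x+y in a bin, x is
Binomial(x+y, q) under the null of proportional means, with q the first
sample's share of the combined library. P-values are Benjamini–Hochberg
adjusted over the bins that received any reads.
"""
from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binning import BinnedCounts
from .io_formats import GeneModel, ReadRecord

logger = logging.getLogger(__name__)

METHOD_TAG = "exact-binomial"  # tags output rows with the test used; see docs/methods.md


def count_distribution(binned: BinnedCounts, normalize: bool = False) -> pd.DataFrame:
    """Frequency of each observed per-bin count value over the whole genome.

    Returns a DataFrame with columns ``count`` and ``frequency`` (number of
    bins, or fraction of bins when ``normalize``).
    """
    flat = binned.flat()
    freq = np.bincount(flat)
    support = np.nonzero(freq)[0]
    values = freq[support].astype(float)
    if normalize:
        values = values / flat.size
    return pd.DataFrame({"count": support, "frequency": values})


def expression_rpkm(gene_counts: np.ndarray, exon_lengths: np.ndarray,
                    library_size: int) -> np.ndarray:
    """Expression RPKM with the +1 cpm pseudocount: (cpm + 1) / kb of exon."""
    gene_counts = np.asarray(gene_counts, dtype=float)
    exon_lengths = np.asarray(exon_lengths, dtype=float)
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if np.any(exon_lengths <= 0):
        raise ValueError("exon lengths must be > 0")
    cpm = gene_counts / (library_size / 1e6)
    return (cpm + 1.0) / (exon_lengths / 1000.0)


def enrichment_rpkm(gene_counts: np.ndarray, span_lengths: np.ndarray,
                    library_size: int) -> np.ndarray:
    """ChIP enrichment RPKM over the full gene span, +0.5 on the RPKM."""
    gene_counts = np.asarray(gene_counts, dtype=float)
    span_lengths = np.asarray(span_lengths, dtype=float)
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if np.any(span_lengths <= 0):
        raise ValueError("span lengths must be > 0")
    cpm = gene_counts / (library_size / 1e6)
    return cpm / (span_lengths / 1000.0) + 0.5


def count_read_centers(reads: Sequence[ReadRecord],
                       intervals: Sequence[tuple[str, int, int]]) -> np.ndarray:
    """Number of read centers falling in each half-open (contig, start, end).

    Same assignment rule as genome binning: a read belongs to an interval iff
    its center lies in [start, end).
    """
    centers: dict[str, np.ndarray] = {}
    by_contig: dict[str, list[int]] = {}
    for r in reads:
        by_contig.setdefault(r.contig, []).append((r.start + r.end - 1) // 2)
    for c, cs in by_contig.items():
        centers[c] = np.sort(np.asarray(cs, dtype=np.int64))
    out = np.zeros(len(intervals), dtype=np.int64)
    for i, (contig, start, end) in enumerate(intervals):
        cs = centers.get(contig)
        if cs is None:
            continue
        out[i] = np.searchsorted(cs, end) - np.searchsorted(cs, start)
    return out


def promoter_interval(gene: GeneModel, contig_length: int,
                      width: int = 4000) -> tuple[str, int, int] | None:
    """The ``width`` bp window centered at the TSS, clipped to the contig.

    Returns None (caller logs and drops the gene) if the clipped window is
    empty.
    """
    half = width // 2
    start = max(0, gene.tss - half)
    end = min(contig_length, gene.tss + width - half)
    if end <= start:
        return None
    return (gene.contig, start, end)


def build_enrichment_table(genes: Sequence[GeneModel],
                           reads_by_sample: dict[str, Sequence[ReadRecord]],
                           contig_lengths: dict[str, int],
                           promoter_width: int = 4000) -> pd.DataFrame:
    """Per-gene pseudocounted enrichment RPKM per sample, body and promoter.

    Genes must already carry ``expression_rpkm``. Output columns:
    ``expression_rpkm`` plus ``{sample}_body`` / ``{sample}_promoter``. All
    values are > 0 by construction of the pseudocounts.
    """
    kept: list[GeneModel] = []
    promoters: list[tuple[str, int, int]] = []
    for g in genes:
        if g.expression_rpkm is None:
            raise ValueError(f"gene {g.gene_id} has no expression_rpkm")
        prom = promoter_interval(g, contig_lengths[g.contig], promoter_width)
        if prom is None:
            logger.warning("gene %s: promoter fully off-contig, dropped", g.gene_id)
            continue
        kept.append(g)
        promoters.append(prom)
    bodies = [(g.contig, g.start, g.end) for g in kept]
    spans = np.array([g.span for g in kept], dtype=float)
    prom_spans = np.array([e - s for _, s, e in promoters], dtype=float)
    table = pd.DataFrame({
        "gene_id": [g.gene_id for g in kept],
        "expression_rpkm": [g.expression_rpkm for g in kept],
    }).set_index("gene_id")
    for sample, reads in reads_by_sample.items():
        lib = len(reads)
        body_counts = count_read_centers(reads, bodies)
        prom_counts = count_read_centers(reads, promoters)
        table[f"{sample}_body"] = enrichment_rpkm(body_counts, spans, lib)
        table[f"{sample}_promoter"] = enrichment_rpkm(prom_counts, prom_spans, lib)
    return table


def ma_stats(x_counts: np.ndarray, y_counts: np.ndarray, lib_x: int, lib_y: int,
             unit_ids: Sequence[str] | None = None,
             pseudocount_cpm: float = 0.5) -> pd.DataFrame:
    """M (log2 fold change) and A (mean log2 intensity) per unit.

    Intensities are cpm-scaled and offset by ``pseudocount_cpm`` so M and A
    stay finite at zero counts.
    """
    x = np.asarray(x_counts, dtype=float)
    y = np.asarray(y_counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError("mismatched unit sets")
    if lib_x <= 0 or lib_y <= 0:
        raise ValueError("library sizes must be > 0")
    u = x / (lib_x / 1e6) + pseudocount_cpm
    v = y / (lib_y / 1e6) + pseudocount_cpm
    m = np.log2(u / v)
    a = (np.log2(u) + np.log2(v)) / 2.0
    if unit_ids is None:
        unit_ids = [str(i) for i in range(len(x))]
    return pd.DataFrame({"unit_id": list(unit_ids), "M": m, "A": a})


def _binom_two_sided(x: int, n: int, q: float, pmf_cache: dict[int, np.ndarray]) -> float:
    """Exact two-sided binomial p-value by summing pmf values <= pmf(x)."""
    pmf = pmf_cache.get(n)
    if pmf is None:
        pmf = stats.binom.pmf(np.arange(n + 1), n, q)
        pmf_cache[n] = pmf
    d = pmf[x] * (1.0 + 1e-7)  # tolerance against float noise in pmf ties
    return float(min(1.0, pmf[pmf <= d].sum()))


def differential_screen(x_counts: np.ndarray, y_counts: np.ndarray,
                        lib_x: int, lib_y: int,
                        unit_ids: Sequence[str] | None = None,
                        fdr_threshold: float = 0.05,
                        pseudocount_cpm: float = 0.5) -> pd.DataFrame:
    """Two-sided exact conditional binomial screen with BH adjustment.

    Units with x + y = 0 are excluded from testing and from the BH
    denominator (their p and fdr are NaN). Output includes M/A, p, fdr, a
    boolean ``significant`` at ``fdr_threshold`` and a ``method`` tag.
    """
    x = np.asarray(x_counts)
    y = np.asarray(y_counts)
    if x.shape != y.shape:
        raise ValueError("mismatched unit sets")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if lib_x + lib_y <= 0:
        raise ValueError("combined library size must be > 0")
    q = lib_x / (lib_x + lib_y)
    n_tot = x + y
    tested = np.nonzero(n_tot > 0)[0]
    pvals = np.full(len(x), np.nan)
    cache: dict[int, np.ndarray] = {}
    for i in tested:
        pvals[i] = _binom_two_sided(int(x[i]), int(n_tot[i]), q, cache)
    fdr = np.full(len(x), np.nan)
    if len(tested):
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]
    out = ma_stats(x, y, lib_x, lib_y, unit_ids, pseudocount_cpm)
    out["x"] = x
    out["y"] = y
    out["p_value"] = pvals
    out["fdr"] = fdr
    out["significant"] = fdr < fdr_threshold
    out["method"] = METHOD_TAG
    return out


def differential_screen_bins(x: BinnedCounts, y: BinnedCounts,
                             fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Per-bin screen between two BinnedCounts sharing a layout."""
    if x.bin_width != y.bin_width or x.contig_lengths != y.contig_lengths:
        raise ValueError("samples disagree on bin layout")
    ids = [f"{c}:{k * x.bin_width}" for c in x.counts for k in range(len(x.counts[c]))]
    return differential_screen(x.flat(), y.flat(), x.library_size, y.library_size,
                               ids, fdr_threshold)


def correlate_expression(table: pd.DataFrame, mark: str, control: str | None = None,
                         region: str = "body") -> float:
    """Pearson r between log enrichment and log expression over genes.

    ``enrichment = mark RPKM`` or, with a control, the ratio
    ``mark RPKM / control RPKM`` in the chosen region (body or promoter).
    The log base is immaterial to Pearson r; natural log is used.
    """
    if region not in ("body", "promoter"):
        raise ValueError(f"region must be body or promoter, got {region!r}")
    if len(table) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    enr = table[f"{mark}_{region}"].to_numpy(dtype=float)
    if control is not None:
        enr = enr / table[f"{control}_{region}"].to_numpy(dtype=float)
    expr = table["expression_rpkm"].to_numpy(dtype=float)
    if np.any(enr <= 0) or np.any(expr <= 0):
        raise ValueError("enrichment and expression must be > 0 (pseudocounted)")
    loge, logx = np.log(enr), np.log(expr)
    if np.ptp(loge) == 0 or np.ptp(logx) == 0:
        raise ValueError("zero variance in log enrichment or log expression")
    return float(stats.pearsonr(loge, logx)[0])


def correlation_summary(table: pd.DataFrame, mark: str,
                        controls: Sequence[str]) -> pd.DataFrame:
    """Table-style correlation summary: mark, controls and ratios x regions."""
    rows = []
    for region in ("body", "promoter"):
        row: dict[str, float | str] = {"region": region}
        for ctrl in controls:
            row[ctrl] = correlate_expression(table, ctrl, None, region)
        row[mark] = correlate_expression(table, mark, None, region)
        for ctrl in controls:
            row[f"{mark}/{ctrl}"] = correlate_expression(table, mark, ctrl, region)
        rows.append(row)
    return pd.DataFrame(rows)
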