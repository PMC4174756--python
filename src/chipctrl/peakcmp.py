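"""Concordance of two externally called peak sets.

Two peaks are *overlapping* when their regions share at least one base pair;
half-open adjacency ([100,200) vs [200,300)) does not count. The overlap
relation drives three summaries: counts of overlapping vs set-unique peaks,
score distributions for the two classes, and the Pearson correlation of the
scores of paired overlapping peaks. Only counts are well defined under the
overlap relation alone; for the score scatter a deterministic pairing is
imposed: each peak of set A is paired with the set-B peak sharing the most
base pairs (ties broken to the leftmost B peak).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Peak


@dataclass
class PeakOverlapResult:
    """Partition of two peak sets by the >= 1 bp overlap relation.

    ``overlap_a``/``only_a`` partition set A (likewise for B); ``pairs`` holds
    one (a, best_b, shared_bp) triple per overlapping A peak.
    """

    pairs: list[tuple[Peak, Peak, int]]
    overlap_a: list[Peak]
    overlap_b: list[Peak]
    only_a: list[Peak]
    only_b: list[Peak]

    @property
    def n_a(self) -> int:
        return len(self.overlap_a) + len(self.only_a)

    @property
    def n_b(self) -> int:
        return len(self.overlap_b) + len(self.only_b)

    @property
    def n_overlap_a(self) -> int:
        return len(self.overlap_a)

    @property
    def n_overlap_b(self) -> int:
        return len(self.overlap_b)


def overlap_peaks(set_a: list[Peak], set_b: list[Peak]) -> PeakOverlapResult:
    """Classify peaks by the >= 1 bp sharing rule and pair A-peaks to B-peaks.

    Inputs are expected coordinate-sorted (the reader guarantees it); the
    result is order-stable given that.
    """
    contigs = sorted({p.contig for p in set_a} | {p.contig for p in set_b})
    pairs: list[tuple[Peak, Peak, int]] = []
    overlap_a: list[Peak] = []
    overlap_b: list[Peak] = []
    only_a: list[Peak] = []
    only_b: list[Peak] = []
    for contig in contigs:
        a = [p for p in set_a if p.contig == contig]
        b = [p for p in set_b if p.contig == contig]
        if not a or not b:
            only_a.extend(a)
            only_b.extend(b)
            continue
        a_start = np.array([p.start for p in a])
        a_end = np.array([p.end for p in a])
        b_start = np.array([p.start for p in b])
        b_end = np.array([p.end for p in b])
        # shared bp of every A x B pair; <= 0 means no overlap
        shared = (np.minimum(a_end[:, None], b_end[None, :])
                  - np.maximum(a_start[:, None], b_start[None, :]))
        hit_a = (shared > 0).any(axis=1)
        hit_b = (shared > 0).any(axis=0)
        overlap_a.extend(p for p, h in zip(a, hit_a) if h)
        overlap_b.extend(p for p, h in zip(b, hit_b) if h)
        only_a.extend(p for p, h in zip(a, hit_a) if not h)
        only_b.extend(p for p, h in zip(b, hit_b) if not h)
        for i in np.nonzero(hit_a)[0]:
            j = int(np.argmax(shared[i]))  # first max = leftmost, b is sorted
            pairs.append((a[i], b[j], int(shared[i, j])))
    return PeakOverlapResult(pairs, overlap_a, overlap_b, only_a, only_b)


def score_correlation(result: PeakOverlapResult) -> float:
    """Pearson r of paired overlapping-peak scores."""
    if len(result.pairs) < 3:
        raise ValueError(f"need >= 3 overlapping pairs, got {len(result.pairs)}")
    sa = np.array([p.score for p, _, _ in result.pairs])
    sb = np.array([q.score for _, q, _ in result.pairs])
    if np.ptp(sa) == 0 or np.ptp(sb) == 0:
        raise ValueError("zero variance in paired peak scores")
    return float(stats.pearsonr(sa, sb)[0])


def score_distributions(result: PeakOverlapResult) -> pd.DataFrame:
    """Long-form peak scores per set ('a'/'b') and overlap status ('o'/'n')."""
    rows = [{"set": s, "status": st, "score": p.score, "sample": p.source_sample}
            for s, st, peaks in (("a", "o", result.overlap_a),
                                 ("a", "n", result.only_a),
                                 ("b", "o", result.overlap_b),
                                 ("b", "n", result.only_b))
            for p in peaks]
    return pd.DataFrame(rows, columns=["set", "status", "score", "sample"])


def concordance_summary(result: PeakOverlapResult) -> dict:
    """Counts plus score r (NaN when fewer than 3 pairs or degenerate)."""
    try:
        r = score_correlation(result)
    except ValueError:
        r = float("nan")
    return {
        "n_a": result.n_a,
        "n_b": result.n_b,
        "n_overlap_a": result.n_overlap_a,
        "n_overlap_b": result.n_overlap_b,
        "n_pairs": len(result.pairs),
        "pearson_r": r,
    }
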