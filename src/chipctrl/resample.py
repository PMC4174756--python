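"""Library-size equalization and the Poisson random reference.

Samples sequenced to different depths are made comparable by binomial
thinning: to match the smallest library N_min, library i keeps each of its
reads independently with probability p_i = N_min / N_i, implemented on bin
counts (a bin with b reads is reassigned a Binomial(b, p_i) draw, which is
distributionally identical to read-level thinning for unordered counts).

For comparison against structureless data, a Poisson reference sample is
generated: bins with zero reads in *every* real sample stay at zero (they are
typically unmappable), and the remaining B bins get i.i.d. Poisson draws with
mean λ = N_min / B, so the expected total matches the thinned libraries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import child_rng
from .binning import BinnedCounts


@dataclass(frozen=True)
class ThinningPlan:
    """Per-sample keep-fractions p_i = N_min / N_i."""

    fractions: dict[str, float]
    n_min: int

    @classmethod
    def from_library_sizes(cls, sizes: dict[str, int]) -> "ThinningPlan":
        if not sizes:
            raise ValueError("no library sizes given")
        if min(sizes.values()) <= 0:
            raise ValueError("library sizes must be positive")
        n_min = min(sizes.values())
        return cls({name: n_min / n for name, n in sizes.items()}, n_min)


def _as_rng(seed: int | np.random.Generator, *names: str) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return child_rng(seed, *names)


def downsample(binned: BinnedCounts, p: float,
               seed: int | np.random.Generator = 0) -> BinnedCounts:
    """Binomially thin every bin count with keep-probability ``p``.

    The returned library_size is the realized post-thinning total, which is
    what downstream per-million scaling should use.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"keep fraction must be in (0, 1], got {p}")
    rng = _as_rng(seed, "downsample", binned.sample_name)
    if p == 1.0:
        new = {c: v.copy() for c, v in binned.counts.items()}
    else:
        new = {c: rng.binomial(v, p) for c, v in binned.counts.items()}
    total = int(sum(int(v.sum()) for v in new.values()))
    return binned.copy_with(new, library_size=total)


def downsample_to_min(samples: Sequence[BinnedCounts],
                      seed: int | np.random.Generator = 0) -> list[BinnedCounts]:
    """Thin every sample to the smallest library among them."""
    plan = ThinningPlan.from_library_sizes({s.sample_name: s.library_size for s in samples})
    out = []
    for s in samples:
        rng = _as_rng(seed, "downsample", s.sample_name) if not isinstance(seed, np.random.Generator) else seed
        out.append(downsample(s, plan.fractions[s.sample_name], rng))
    return out


def poisson_null(all_samples: Sequence[BinnedCounts], n_min: int | None = None,
                 seed: int | np.random.Generator = 0) -> BinnedCounts:
    """Generate the Poisson random reference over the observed bin support.

    Bins with no reads in any input sample are assigned no reads; the
    remaining B bins get i.i.d. Poisson(λ) counts with λ = n_min / B.
    ``n_min`` defaults to the smallest input library size.
    """
    if not all_samples:
        raise ValueError("need at least one sample")
    first = all_samples[0]
    for s in all_samples[1:]:
        if s.bin_width != first.bin_width or s.contig_lengths != first.contig_lengths:
            raise ValueError("samples disagree on bin layout")
    if n_min is None:
        n_min = min(s.library_size for s in all_samples)
    masks = {c: np.zeros(len(first.counts[c]), dtype=bool) for c in first.counts}
    for s in all_samples:
        for c, vec in s.counts.items():
            masks[c] |= vec > 0
    B = int(sum(int(m.sum()) for m in masks.values()))
    if B == 0:
        raise ValueError("no bin has a read in any sample (B = 0)")
    lam = n_min / B
    rng = _as_rng(seed, "poisson_null")
    counts = {}
    for c, m in masks.items():
        vec = np.zeros(len(m), dtype=np.int64)
        vec[m] = rng.poisson(lam, size=int(m.sum()))
        counts[c] = vec
    total = int(sum(int(v.sum()) for v in counts.values()))
    return BinnedCounts("poisson_null", first.bin_width, counts, total,
                        dict(first.contig_lengths))
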