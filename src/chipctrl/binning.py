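"""Fixed-width genome binning of read centers.

Reads (already MAPQ-filtered) are assigned to consecutive, non-overlapping
bins of a fixed width — 100 bp for coverage profiling, 1000 bp for count
distributions and differential screening — based on the center of the read.
Each read increments exactly one bin; strand is ignored. The center of an
even-length read is the lower of the two middle positions, so counts are
fully reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import ReadRecord


@dataclass
class BinnedCounts:
    """Per-contig integer count vectors at a fixed bin width.

    Bin ``k`` of a contig covers ``[k*bin_width, (k+1)*bin_width)``; the last
    bin may be genomically shorter but is treated as nominal width throughout.
    ``library_size`` is the total number of retained reads the counts came
    from (it can exceed the bin-count total only after downsampling, where it
    is redefined as the post-thinning total).
    """

    sample_name: str
    bin_width: int
    counts: dict[str, np.ndarray]
    library_size: int
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for contig, vec in self.counts.items():
            expected = n_bins(self.contig_lengths[contig], self.bin_width)
            if len(vec) != expected:
                raise ValueError(
                    f"{contig}: {len(vec)} bins, expected {expected} for "
                    f"length {self.contig_lengths[contig]} at width {self.bin_width}")

    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.counts.values()))

    def flat(self) -> np.ndarray:
        """All bins concatenated in contig-dict order."""
        return np.concatenate([self.counts[c] for c in self.counts])

    def copy_with(self, counts: dict[str, np.ndarray], *, sample_name: str | None = None,
                  library_size: int | None = None) -> "BinnedCounts":
        return BinnedCounts(
            sample_name=self.sample_name if sample_name is None else sample_name,
            bin_width=self.bin_width,
            counts=counts,
            library_size=self.library_size if library_size is None else library_size,
            contig_lengths=dict(self.contig_lengths),
        )


def n_bins(contig_length: int, bin_width: int) -> int:
    return -(-contig_length // bin_width)


def bin_reads(reads: Iterable[ReadRecord], contig_lengths: dict[str, int],
              bin_width: int, sample_name: str = "sample") -> BinnedCounts:
    """Count read centers into fixed-width bins.

    A read on an unknown contig, or whose center lies at or beyond the stated
    contig length, is an error (it indicates inconsistent annotation, not
    something to silently drop).
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    counts = {c: np.zeros(n_bins(length, bin_width), dtype=np.int64)
              for c, length in contig_lengths.items()}
    total = 0
    # group centers per contig to vectorize the bincount
    centers: dict[str, list[int]] = {c: [] for c in contig_lengths}
    for r in reads:
        if r.contig not in contig_lengths:
            raise ValueError(f"read on unknown contig {r.contig!r}")
        center = (r.start + r.end - 1) // 2
        if center < 0 or center >= contig_lengths[r.contig]:
            raise ValueError(
                f"read center {center} outside contig {r.contig} "
                f"(length {contig_lengths[r.contig]})")
        centers[r.contig].append(center)
        total += 1
    for contig, cs in centers.items():
        if cs:
            idx = np.asarray(cs, dtype=np.int64) // bin_width
            counts[contig] += np.bincount(idx, minlength=len(counts[contig]))
    return BinnedCounts(sample_name, bin_width, counts, total, dict(contig_lengths))


def rebin(binned: BinnedCounts, factor: int) -> BinnedCounts:
    """Aggregate adjacent bins: new bin k = sum of old bins [k*factor, (k+1)*factor).

    Equivalent to re-binning the original reads at width*factor, since
    floor(floor(c/w)/f) == floor(c/(w*f)).
    """
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor == 1:
        return binned.copy_with({c: v.copy() for c, v in binned.counts.items()})
    new_width = binned.bin_width * factor
    new_counts = {}
    for contig, vec in binned.counts.items():
        m = n_bins(binned.contig_lengths[contig], new_width)
        padded = np.zeros(m * factor, dtype=vec.dtype)
        padded[:len(vec)] = vec
        new_counts[contig] = padded.reshape(m, factor).sum(axis=1)
    return BinnedCounts(binned.sample_name, new_width, new_counts,
                        binned.library_size, dict(binned.contig_lengths))


def bin_coverage_rpkm(binned: BinnedCounts) -> dict[str, np.ndarray]:
    """Per-bin read density in RPKM: count / (library_size/1e6) / (bin_width/1000)."""
    if binned.library_size <= 0:
        raise ValueError("library_size must be > 0 for RPKM")
    per_million = binned.library_size / 1e6
    per_kb = binned.bin_width / 1000.0
    return {c: v / per_million / per_kb for c, v in binned.counts.items()}


def write_bincounts(path: str | Path, binned: BinnedCounts) -> None:
    """TSV of per-bin counts with metadata header comments."""
    with open(path, "w") as fh:
        fh.write(f"# sample={binned.sample_name}\n")
        fh.write(f"# bin_width={binned.bin_width}\n")
        fh.write(f"# library_size={binned.library_size}\n")
        for contig, length in binned.contig_lengths.items():
            fh.write(f"# contig={contig}:{length}\n")
        fh.write("contig\tstart\tcount\n")
        for contig, vec in binned.counts.items():
            w = binned.bin_width
            for k, v in enumerate(vec):
                fh.write(f"{contig}\t{k * w}\t{int(v)}\n")


def read_bincounts(path: str | Path) -> BinnedCounts:
    sample, bin_width, library_size = "sample", None, None
    contig_lengths: dict[str, int] = {}
    rows: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                key = key.strip()
                if key == "sample":
                    sample = value
                elif key == "bin_width":
                    bin_width = int(value)
                elif key == "library_size":
                    library_size = int(value)
                elif key == "contig":
                    name, _, length = value.partition(":")
                    contig_lengths[name] = int(length)
                continue
            if line.startswith("contig\t") or not line.strip():
                continue
            contig, _start, count = line.rstrip("\n").split("\t")
            rows.setdefault(contig, []).append(int(count))
    if bin_width is None or library_size is None:
        raise ValueError(f"{path}: missing bin_width/library_size metadata")
    counts = {c: np.asarray(v, dtype=np.int64) for c, v in rows.items()}
    return BinnedCounts(sample, bin_width, counts, library_size, contig_lengths)


def write_bedgraph(path: str | Path, binned: BinnedCounts,
                   values: dict[str, np.ndarray] | None = None) -> None:
    """bedGraph export of per-bin counts (or supplied values, e.g. RPKM)."""
    data = values if values is not None else binned.counts
    with open(path, "w") as fh:
        for contig, vec in data.items():
            w = binned.bin_width
            length = binned.contig_lengths[contig]
            for k, v in enumerate(vec):
                end = min((k + 1) * w, length)
                fh.write(f"{contig}\t{k * w}\t{end}\t{v:g}\n")
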