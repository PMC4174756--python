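"""Readers and writers for the interval and table formats the pipeline touches.

All genomic coordinates are 0-based, half-open (BED convention) everywhere in
the package. GTF input, which is 1-based inclusive, is converted on read.
Downstream modules consume only the types defined here, never raw files.

Formats handled:

* BED6 for aligned reads (the score column carries the mapping quality);
* GTF2/GFF3 or a simple TSV for gene models;
* ENCODE narrowPeak / BED5 for externally called peaks;
* two-column ``chrom.sizes`` TSV for contig lengths;
* TSV with header for expression counts.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: MAPQ threshold used throughout: reads with mapping quality below 20 are
#: discarded before any counting.
DEFAULT_MAPQ_MIN = 20


class ParseError(ValueError):
    """Raised for malformed input lines; message names the file and line."""


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read as a genomic interval.

    ``start``/``end`` are 0-based half-open; ``mapq`` is the Phred-scaled
    mapping quality the MAPQ filter operates on.
    """

    contig: str
    start: int
    end: int
    strand: str
    mapq: int

    @property
    def center(self) -> int:
        """Read center; the lower of the two middle bases for even lengths."""
        return (self.start + self.end - 1) // 2


@dataclass
class GeneModel:
    """Gene coordinates plus the exon length used for expression RPKM.

    ``exon_length`` is the width of the union of the gene's exons (introns
    excluded); the full span ``end - start`` (introns included) is what
    enrichment RPKM uses. ``expression_rpkm`` is filled in by the enrichment
    module once expression counts are available.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    exon_length: int
    expression_rpkm: float | None = None

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site: ``start`` on +, ``end - 1`` on −."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Peak:
    """A scored interval from an external peak caller (e.g. MACS)."""

    contig: str
    start: int
    end: int
    score: float
    source_sample: str


def _split(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_bed_reads(path: str | Path, mapq_min: int = DEFAULT_MAPQ_MIN) -> list[ReadRecord]:
    """Read a BED6 file of aligned reads, keeping records with mapq >= mapq_min.

    Columns: chrom, start, end, name, score (interpreted as MAPQ), strand.
    Records failing the filter are counted and logged, not returned.
    """
    path = Path(path)
    kept: list[ReadRecord] = []
    discarded = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split(line)
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BED columns, got {len(fields)}")
            contig, start_s, end_s, _name, mapq_s, strand = fields[:6]
            try:
                start, end, mapq = int(start_s), int(end_s), int(mapq_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate or mapq") from exc
            if not contig:
                raise ParseError(f"{path}:{lineno}: empty contig name")
            if end <= start:
                raise ParseError(f"{path}:{lineno}: empty or inverted interval [{start}, {end})")
            if mapq < 0:
                raise ParseError(f"{path}:{lineno}: negative mapq {mapq}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            if mapq >= mapq_min:
                kept.append(ReadRecord(contig, start, end, strand, mapq))
            else:
                discarded += 1
    logger.info("read_bed_reads(%s): kept %d reads, discarded %d with mapq < %d",
                path.name, len(kept), discarded, mapq_min)
    return kept


def read_bam_reads(path: str | Path, mapq_min: int = DEFAULT_MAPQ_MIN) -> list[ReadRecord]:
    """Read aligned reads from SAM/BAM behind the same contract as BED.

    Unmapped records are skipped; mapq comes from the alignment record. BED
    remains the reference path (and the one the fixtures use); this reader
    exists so real alignments need no conversion step.
    """
    import pysam

    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    kept: list[ReadRecord] = []
    discarded = 0
    with pysam.AlignmentFile(str(path), mode) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            if aln.mapping_quality >= mapq_min:
                kept.append(ReadRecord(aln.reference_name, aln.reference_start,
                                       aln.reference_end,
                                       "-" if aln.is_reverse else "+",
                                       aln.mapping_quality))
            else:
                discarded += 1
    logger.info("read_bam_reads(%s): kept %d reads, discarded %d with mapq < %d",
                path.name, len(kept), discarded, mapq_min)
    return kept


def write_bed_reads(path: str | Path, reads: Iterable[ReadRecord]) -> None:
    """Write reads as BED6 (name = r<i>, score column = MAPQ)."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\tr{i}\t{r.mapq}\t{r.strand}\n")


_GTF_GENE_ID = re.compile(r'gene_id[ =]+"?([^";]+)"?')


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total width of the union of half-open intervals."""
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def _read_genes_gtf(path: Path) -> list[GeneModel]:
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split(line)
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
            contig, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                raise ParseError(f"{path}:{lineno}: exon without gene_id attribute")
            gid = m.group(1)
            # GTF is 1-based inclusive; convert to 0-based half-open.
            start, end = int(start_s) - 1, int(end_s)
            if end <= start:
                raise ParseError(f"{path}:{lineno}: empty exon interval")
            exons.setdefault(gid, []).append((start, end))
            prev = meta.setdefault(gid, (contig, strand))
            if prev != (contig, strand):
                raise ParseError(f"{path}:{lineno}: gene {gid} spans contigs or strands")
    genes = []
    for gid, ivals in exons.items():
        contig, strand = meta[gid]
        start = min(s for s, _ in ivals)
        end = max(e for _, e in ivals)
        genes.append(GeneModel(gid, contig, start, end, strand, _merged_length(ivals)))
    genes.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return genes


_GENE_TSV_COLS = ["gene_id", "contig", "start", "end", "strand", "exon_length"]


def _read_genes_tsv(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = _split(next(fh))
        idx = {c: header.index(c) for c in _GENE_TSV_COLS if c in header}
        missing = [c for c in _GENE_TSV_COLS if c not in idx]
        if missing:
            raise ParseError(f"{path}: missing gene table columns {missing}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split(line)
            gid = fields[idx["gene_id"]]
            if gid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            seen.add(gid)
            start = int(fields[idx["start"]])
            end = int(fields[idx["end"]])
            exon_length = int(fields[idx["exon_length"]])
            if end <= start:
                raise ParseError(f"{path}:{lineno}: empty gene interval")
            if exon_length > end - start:
                raise ParseError(
                    f"{path}:{lineno}: exon_length {exon_length} exceeds gene span {end - start}")
            if exon_length <= 0:
                raise ParseError(f"{path}:{lineno}: nonpositive exon_length")
            genes.append(GeneModel(gid, fields[idx["contig"]], start, end,
                                   fields[idx["strand"]], exon_length))
    return genes


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF/GFF (by extension) or a header TSV.

    For GTF input the exon length is the width of the *union* of each gene's
    exon intervals and the gene span is the min/max over exons.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        return _read_genes_gtf(path)
    return _read_genes_tsv(path)


def write_gene_table(path: str | Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_TSV_COLS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.contig}\t{g.start}\t{g.end}\t{g.strand}\t{g.exon_length}\n")


def read_peaks(path: str | Path, source_sample: str,
               score_column: str = "score") -> list[Peak]:
    """Read narrowPeak or BED5 peaks, sorted by (contig, start, end).

    ``score_column`` selects BED column 5 (``"score"``, the default) or
    narrowPeak column 9 (``"qvalue"``, the −log10 q-value). Overlapping peaks
    within one file are kept as-is, never merged.
    """
    if score_column not in ("score", "qvalue"):
        raise ValueError(f"score_column must be 'score' or 'qvalue', got {score_column!r}")
    path = Path(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = _split(line)
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >= 5 columns")
            col = 4 if score_column == "score" else 8
            if col >= len(fields):
                raise ParseError(
                    f"{path}:{lineno}: score_column={score_column!r} needs column {col + 1}, "
                    f"file has {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[col])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate or score") from exc
            if end <= start:
                raise ParseError(f"{path}:{lineno}: empty peak interval")
            if not (score == score and abs(score) != float("inf")):
                raise ParseError(f"{path}:{lineno}: non-finite score")
            peaks.append(Peak(fields[0], start, end, score, source_sample))
    peaks.sort(key=lambda p: (p.contig, p.start, p.end))
    return peaks


def write_peaks(path: str | Path, peaks: Sequence[Peak]) -> None:
    """Write peaks as narrowPeak (col 5 = score, col 9 = score, peak = -1)."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\tpeak{i}\t{p.score:g}\t."
                     f"\t0\t-1\t{p.score:g}\t-1\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column contig<TAB>length table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split(line)
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected contig<TAB>length")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(path: str | Path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for contig, length in sizes.items():
            fh.write(f"{contig}\t{length}\n")


def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read a TSV with columns ``gene_id`` and ``count`` (or ``rpkm``).

    Returns gene_id -> value for whichever value column is present
    (``count`` preferred when both exist).
    """
    path = Path(path)
    values: dict[str, float] = {}
    with open(path) as fh:
        header = _split(next(fh))
        if "gene_id" not in header:
            raise ParseError(f"{path}: expression table needs a gene_id column")
        value_col = "count" if "count" in header else "rpkm" if "rpkm" in header else None
        if value_col is None:
            raise ParseError(f"{path}: expression table needs a count or rpkm column")
        gi, vi = header.index("gene_id"), header.index(value_col)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = _split(line)
            gid = fields[gi]
            if gid in values:
                raise ParseError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
            values[gid] = float(fields[vi])
    return values
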