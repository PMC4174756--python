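# Methods

## Scope and model

The package compares two ChIP-seq background controls — whole-cell extract
(WCE) and a Histone H3 pull-down — against a repressive histone mark
(H3K27me3) and expression data. All analyses operate on aligned reads
reduced to intervals (BED), binned genome-wide by read center, and on
per-gene summaries; no sequence-level modeling is attempted. Coordinates are
0-based half-open throughout; GTF input is converted on read. The TSS is
`start` on the + strand and `end − 1` on the − strand.

### Binning

Reads with mapping quality below 20 are discarded. Each surviving read
increments exactly one bin: index `floor(center / w)` with
`center = floor((start + end − 1)/2)` — the lower of the two middle bases
for even-length reads, a deterministic convention that makes counts
reproducible (and the only place where mirror symmetry is broken by one
base). 100 bp bins serve coverage profiling, 1000 bp bins the distribution
and screening analyses. The final partial bin of a contig is kept at nominal
width for RPKM purposes; at the scales involved this is negligible.

### Depth matching and the Poisson reference

To compare count distributions across libraries of different depth, each
library i keeps a fraction pᵢ = N_min/Nᵢ of its reads, implemented as
independent Binomial(b, pᵢ) draws per bin — distributionally identical to
read-level thinning for unordered counts. The random reference assigns no
reads to bins that are empty in every sample (unmappable-like regions) and
i.i.d. Poisson(λ = N_min/B) counts to the remaining B bins, so its expected
total matches the thinned libraries. λ uses the realized post-filter N_min,
not nominal depth.

### Differential screen

The two controls are unreplicated, so instead of a moderated-variance model
the screen uses the exact conditional binomial test: given n = x + y reads
in a bin, x ~ Binomial(n, q) under the null of proportional means, with
q the first library's share of the combined depth. Two-sided p-values sum
all outcomes whose probability does not exceed pmf(x) (with a 1e−7 relative
tolerance against floating-point ties). Bins with n = 0 are excluded from
testing and from the Benjamini–Hochberg denominator. The output carries a
`method: exact-binomial` tag so results cannot be mistaken for a
moderated-variance analysis; the test is conservative for discrete counts,
which the calibration test allows for. MA statistics use cpm-scaled
intensities with a configurable pseudocount (default 0.5 cpm — a documented
choice, not a published value).

### RPKM conventions

Two deliberately different pseudocounts:

* expression: `rpkm = (cpm + 1) / (exon_kb)` — one count per million is
  added before dividing by the exon length;
* ChIP enrichment: `rpkm = cpm / span_kb + 0.5` over the full gene span
  (introns included), or over the fixed 4 kb promoter centered at the TSS.
  Adding on the RPKM scale evens out background levels between samples.

Gene and promoter read counts use the same read-center rule as binning, so
a read belongs to at most one adjacent interval. Promoters are clipped at
contig edges; a gene whose promoter is entirely off-contig is dropped with
a warning.

### Metagene profiles

Each gene of width w gets 150 bins of width w/50 covering [start − w,
end + w), strand-oriented so index 0 is most upstream and index 50 starts
at the TSS. A gene bin's coverage is the *unweighted* mean RPKM of every
100 bp genome bin it overlaps by any amount (a length-weighted variant is
available behind a flag). Genes are split into expression quartiles
(stable sort by expression then gene id; remainders go to the lowest
quartiles) after excluding genes with expression RPKM > 100, which would
otherwise dominate a linear-scale mean. Profiles are smoothed by a 3-bin
running mean, truncated to the existing neighbors at the edges. Ratio
profiles divide smoothed mark by smoothed control position-wise, with an
optional floor on the control. TSS-centered profiles use fixed ±2 kb
windows in 100 bp steps (an even position count, so no bin straddles the
TSS); extent and step are configurable since no single convention exists.
Genes whose profile or TSS window would leave the contig are skipped with a
warning; genes narrower than 50 bp (bin width < 1 bp) are likewise
excluded.

Dip metrics: the dip position is the argmin of the smoothed top-quartile
profile; dip depth is `1 − mean(center)/mean(flanks)` with a narrow center
(positions 49–51) for localizing a sharp dip and, for ratio-cancellation
assessments, a window spanning the whole dip support (positions 45–55
against flanks 35–44/56–65) — averaging over the support is what keeps the
estimate stable against counting noise at desk-scale depth.

### Peak concordance

Peaks from an external caller are read from narrowPeak/BED5 (score column 5
by default; the −log10 q column 9 is selectable, since published analyses
do not always state which score they plot). Two peaks overlap when they
share at least one base pair; adjacency under half-open coordinates does
not count. Counts of overlapping vs set-unique peaks are symmetric by
construction; for the score scatter each A-peak is paired with the B-peak
sharing the most bases (leftmost on ties) — a deterministic convention the
concordance counts do not depend on.

## Synthetic data generator

The generator emulates the features the analyses are sensitive to, at
10 bp density resolution, with defaults chosen once as a realistic desk
scale:

| parameter | default | why |
|---|---|---|
| genome | 3 × 2 Mb + 20 kb chrM analog | smallest genome with thousands of 1 kb bins per contig plus a separate histone-free contig |
| genes | 300, lognormal width (median 5 kb, σ_log 0.4, clipped 1.5–20 kb) | enough genes for stable quartile means at realistic mammalian gene sizes |
| expression | lognormal RPKM (median 5, σ_log 1.5) | a heavy right tail so a few genes exceed the RPKM > 100 exclusion, as ribosomal/mitochondrial genes do |
| libraries | WCE 240 k; H3 150/160 k; H3K27me3 180/190/200 k reads | a typical replicate design for this comparison (1 WCE, 2 H3, 3 mark) with WCE deepest, at roughly 1/100 of real depth |
| fragment length | 200 bp | typical sonicated ChIP fragment |
| TSS dip | depth 0.8 × expression rank, σ 100–250 bp | nucleosome-free region grows with expression |
| WCE TSS peak | 3 × expression rank, σ 150 bp | nucleosome-free DNA over-represented in sheared extract |
| gene-body boost | 0.5 × expression rank (both controls) | both controls are somewhat enriched over highly expressed genes |
| chrM factor | WCE 8×, H3/H3K27me3 0 | mitochondrial DNA carries no histones; WCE is strongly enriched there |
| hotspots | 30 × 1 kb at 10× baseline, all samples | repeat-like bins with large counts but no fold change between controls |
| modification | logistic in log expression, 0.05–0.8, slope −1, 3 kb Gaussian domain decay | repressive mark anti-correlated with expression; domains bleed smoothly past gene edges so the mark/occupancy ratio is locally constant across the TSS |
| MAPQ | 10% of reads below 20 | exercises the filter |

H3 density is proportional to occupancy (baseline × body boost × dip,
plus hotspots, zero on chrM); H3K27me3 is occupancy × modification
fraction; WCE is baseline + boost + hotspots + TSS peaks, flat where H3
dips. Each density is normalized to integrate to 1; fragment midpoints are
drawn by inverse CDF, midpoints whose fragment would leave the contig are
redrawn. Gene placement is sequential per contig with a margin of one gene
width on each side (so every profile window stays on-contig and
modification domains do not pile up at a neighbor's TSS) and random slack
distribution; it succeeds for any seed whenever the genome can hold the
genes. Expression is emitted as per-gene Poisson counts around the expected
RPKM at a nominal 10⁶-read RNA library — the RNA side only ranks genes, so
count-level simulation suffices.

One root seed drives everything; every stochastic operation derives a child
stream from (seed, operation, sample) via hashed spawn keys, so adding a
sample never perturbs another sample's draws, and reruns are byte-identical.

**What the generator does not emulate:** mappability and GC bias, PCR
duplicates, fragment-length variation, overlapping or nested genes,
chromatin-domain autocorrelation beyond the configured features, and any
sequence-level effect. Passing tests therefore demonstrate that the
*pipeline machinery* recovers planted structure of realistic shape and
magnitude — not that real libraries will show effects of these exact sizes.

## Pipeline and determinism

The report chains the stages in order (distributions, screens, optional
peak concordance, profiles, correlations) and writes TSVs with a fixed
`%.6g` float format plus a manifest with the seed and a config hash.
Intermediates are recomputed on rerun rather than cached: every stage is
seconds at desk scale, and recomputation is what the byte-identity
guarantee rests on. Replicates are merged per sample kind before profiling
and screening; per-replicate analyses are available through the library.

## Known limitations

* The exact binomial screen does not borrow variance strength across
  replicates; with replicated data a moderated-variance model would be more
  powerful.
* Unweighted gene-bin/genome-bin averaging slightly blurs features narrower
  than 100 bp; the length-weighted variant reduces this at the cost of
  departing from the stated averaging rule.
* The downsampling flag is per-analysis: ON for distribution curves, OFF
  for RPKM-normalized analyses (which carry their own per-million scaling);
  there is no single canonical list of which analyses must be thinned.
* Peak calling is consumed, never performed; synthetic narrowPeak fixtures
  stand in for caller output and are labeled as such.
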