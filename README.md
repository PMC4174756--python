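# chipctrl — comparing ChIP-seq background controls

ChIP-seq of a histone modification needs a background control to separate
true enrichment from non-uniform background reads. The two candidates are
whole-cell extract (WCE, "input") — sheared chromatin sampled before
immunoprecipitation — and a Histone H3 pull-down, which maps nucleosome
occupancy itself. This package implements, as a tested pipeline, the
analyses by which the two controls are compared against an H3K27me3
(repressive mark) sample and RNA-seq expression:

1. **Count distributions** — reads with MAPQ ≥ 20 are assigned to 1 kb bins
   by read center; deeper libraries are thinned to the smallest by binomial
   resampling (each bin count b is replaced by a draw from B(b, pᵢ) with
   pᵢ = N_min/Nᵢ) and compared with a Poisson reference in which bins empty
   in every sample stay empty and the remaining B bins receive i.i.d.
   Poisson(λ = N_min/B) counts. Heavier-than-Poisson tails reveal enriched
   structure in the controls.
2. **Differential screen** — per 1 kb bin (and per gene), WCE vs H3 counts
   are tested with a two-sided exact conditional binomial test
   (x | x+y ~ B(x+y, N_x/(N_x+N_y))), Benjamini–Hochberg adjusted; results
   are reported as MA statistics (M = log₂ fold change, A = mean log₂
   intensity, with a 0.5-cpm pseudocount).
3. **Peak concordance** — externally called peak sets are classified as
   overlapping when they share ≥ 1 bp (half-open adjacency does not count);
   scores of paired overlapping peaks are Pearson-correlated.
4. **Metagene profiles** — each gene gets 150 bins of width w/50 covering
   the gene ± one gene width; bin coverage is the unweighted mean RPKM of
   the overlapping 100 bp genome bins, averaged within expression quartiles
   and smoothed with a 3-bin running mean; genes with expression RPKM > 100
   are excluded. TSS-centered (±2 kb) and mark/control ratio profiles use
   the same machinery.
5. **Enrichment–expression correlation** — expression RPKM uses the exon
   length with a +1 cpm pseudocount ((cpm+1)/kb); ChIP enrichment RPKM uses
   the full gene span (or the 4 kb promoter centered at the TSS) with +0.5
   added to the RPKM. Pearson r is computed between log enrichment (plain or
   mark/control ratio) and log expression.

A synthetic-data module generates BED read sets with the structure real
controls show — library-size differences, a histone-free mitochondrial
analog enriched only in WCE, shared repeat-like hotspots, a nucleosome-free
TSS dip in H3/H3K27me3 and a TSS peak in WCE that grow with expression, and
an H3K27me3 modification fraction decreasing in expression — so the whole
pipeline runs and is verified at desk scale (6 Mb genome, 300 genes,
~2×10⁵ reads per sample, seconds per stage).

## Worked example

```bash
chipctrl simulate --seed 1 --out data/
chipctrl report --data-dir data/ --out report/
```

or equivalently, step by step with the numbered drivers:

```bash
cd analysis
python 01_simulate.py --seed 1
python 05_metagene_profiles.py --seed 1
python 06_expression_correlation.py --seed 1
```

which prints (seed 1):

```
top expression quartile, gene-scaled profiles (TSS = position 0):
  H3 minimum at position -1, dip depth 0.48
  H3K27me3 dip depth 0.30
  H3K27me3/H3 deviation across the TSS 0.7% (dip canceled)
  H3K27me3/WCE dip depth 0.53 (dip reinforced)

Pearson r between log enrichment and log expression:
  region   WCE    H3  H3K27me3  H3K27me3/WCE  H3K27me3/H3
    body 0.544 0.397    -0.910        -0.948       -0.945
promoter 0.494 0.110    -0.906        -0.942       -0.941
```

Reading: the H3 profile dips exactly at the TSS of expressed genes
(nucleosome-free region); dividing the mark by H3 cancels the dip — the mark
and H3 share the same occupancy source — while dividing by WCE, which peaks
at the TSS, deepens it. Both controls correlate positively with expression,
so either ratio strengthens the mark's anti-correlation with expression
(−0.91 → −0.95). The remaining drivers cover the count-distribution,
differential-screen and peak-concordance analyses; small result tables land
under `results/`, bulky read data under `scratch/`.

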