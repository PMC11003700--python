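# peakreg

Integrative ChIP-seq/RNA-seq regulatory classification for transcription
factors that act through both promoters and enhancers.

Amplified MYC-family factors in cancer (the motivating case is MYCN in
neuroblastoma) bind two kinds of regulatory elements with different
consequences: promoters of canonical growth/ribosome-biogenesis targets
they activate, and distal enhancers of differentiation genes they
repress together with corepressors. Dissecting which is which requires
stitching several analyses together: chromatin-state segmentation of the
TF's binding sites, positional promoter/enhancer assignment,
super-enhancer calling, cofactor co-binding and knockdown occupancy
changes, integration with differential expression, and — once candidate
cofactors emerge as drug targets — checkerboard synergy scoring. peakreg
implements that whole chain as a tested, reusable library plus CLI, and
ships a synthetic-data generator with machine-readable ground truth so
every stage can be validated end-to-end without any download.

## The analyses

**Signal matrices and RPKM.** Coverage is binned around each peak anchor
(summit if called, else midpoint): bins of 10 bp tiling ±3 kb, each bin
the mean per-base signal. Scores are reads per kilobase per million
mapped reads,

&nbsp;&nbsp;RPKM = count / ((L/1000) · (N/10⁶)),

with L the region length and N the library size. The "peak-center score"
of a binding site is the accumulated signal over ±500 bp (100 bins); a
metagene profile is the per-bin mean across peaks.

**Chromatin-state segmentation.** TF peaks are k-means clustered (k = 2)
on the concatenated H3K4me3 / H3K4me1 / H3K27ac matrices (log1p,
standardized per mark). The cluster with the higher mean
H3K4me3/H3K4me1 peak-center ratio is *promoter-like*, the other
*enhancer-like*. Active enhancers are independently defined as H3K27ac
peaks with no H3K4me3 overlap.

**Positional annotation.** The promoter window is −1 kb…+100 bp around
the TSS, strand-aware. A peak overlapping any promoter window is
promoter-class and is assigned to the overlapping gene with the nearest
TSS; otherwise it is distal and assigned to the nearest TSS overall,
with strand-aware signed distances and a 5-kb near-TSS distribution
summary.

**Peak-set overlap.** Two peak sets are compared by building the
bipartite overlap graph (≥1 bp) and counting connected components; the
number of "common" peaks is Σ min(|A side|, |B side|) over components,
which is symmetric in the two sets.

**Super-enhancers.** Distal (>2.5 kb from any TSS) H3K27ac peaks are
stitched when gaps are ≤12.5 kb; each stitched region is scored by the
input-subtracted RPKM summed over its constituents; regions are rank
ordered, both axes scaled to [0, 1], and the cutoff sits where the
tangent slope of the rank curve reaches 1 — regions above it are
super-enhancers.

**Regulatory quadrants.** Genes with |fold change| ≥ 1.5 and adjusted
p < 0.05 after TF knockdown are crossed with the element class at which
the TF binds them, giving promoter-down / promoter-up / enhancer-down /
enhancer-up counts and within-class percentages (a dual-bound gene
counts in both classes).

**Occupancy changes.** Per-peak knockdown/control score ratios are
binned: down (≤1/1.2), stable (within 1.1-fold), up (≥1.2), with the two
uncovered ratio bands reported explicitly as unclassified. Class
distributions between conditions are compared by a 2×2 Pearson
chi-square without continuity correction.

**Bliss synergy.** For a dose checkerboard of viabilities (% of
untreated), each combination cell's excess over the Bliss independence
expectation E = e_a + e_b − e_a·e_b is computed in percentage points;
the average over combination cells classifies the pair as additive
(−10, 10], synergistic (>10), or antagonistic (≤−10).

## Worked example

```
$ peakreg generate --seed 1 --out demo
wrote synthetic dataset (seed 1) to demo: 138 TF peaks, 200 genes

$ peakreg run-all --data-dir demo --out demo_run
{
 "clusters": {"k": 2, "n_promoter_like": 78, "n_enhancer_like": 60},
 "annotation": {
  "promoter": {"count": 78, "percent": 56.5},
  "distal": {"count": 60, "percent": 43.5}
 },
 "quadrants": {
  "promoter_down": 60, "promoter_up": 10,
  "enhancer_down": 0, "enhancer_up": 60
 },
 "super_enhancers": 1,
 "occupancy": {
  "cofactor_b": {"down": 30, "stable": 20, "up": 10, "unclassified": 0},
  "tf_summit_decrease_percent": 49.9,
  "cofactor_a_summit_decrease_percent": 5.0
 },
 "synergy": {
  "combo_excess_0":  {"average_score": -0.0, "classification": "additive"},
  "combo_excess_15": {"average_score": 15.0, "classification": "synergistic"}
 }
}
```

Reading the numbers: the 138 TF peaks segment into 78 promoter-like and
60 enhancer-like sites, matching the positional promoter/distal split
(56.5% / 43.5%). Crossing binding with the knockdown DE table, genes
bound at promoters are predominantly down-regulated on TF loss (60 vs
10) while enhancer-bound genes go up (60 vs 0) — the planted asymmetry
between activated canonical targets and repressed differentiation
genes. The enhancer-restricted cofactor loses occupancy at half its
sites (30 down / 20 stable / 10 up), TF signal at peak summits drops by
~50% and the promoter cofactor's by ~5%, and the dose matrix with a
planted 15-point Bliss excess scores 15.0 (synergistic) while the
independent one scores 0 (additive). Every stage is also available as a
standalone subcommand (`matrix`, `cluster`, `annotate`, `overlap`,
`superenh`, `integrate`, `occupancy`, `synergy`) on the documented text
formats (narrowPeak/BED6, bedGraph, TSV, CSV); `demo_run/` receives
`report.json` plus a `manifest.json` with input digests and stage
counts. The full truth for the generated dataset is in `demo/truth.json`.

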