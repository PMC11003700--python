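# Methods

This note documents the models and procedures implemented in peakreg,
the parameters that matter, the numerical choices made where a published
convention does not pin one down, and what the synthetic data generator
does and does not emulate.

## Coordinates and units

All genomic intervals are 0-based, half-open `[start, end)` (BED
convention); the minus-strand TSS is `end − 1`. Coverage tracks are step
functions with implicit zeros in gaps, carried together with the
library's total mapped-read count. Signal is normalized as RPKM,
`count / ((L/1000)·(N/10⁶))`; wherever a "read count" over a region is
needed from a coverage track, the per-base coverage integral stands in
for it (the two differ by a constant factor — mean read length — which
cancels in every comparison the pipeline makes: rankings, ratios, and
input subtraction at matched scale).

## Signal matrices

`compute_matrix` anchors each peak at its called summit when present,
else the interval midpoint ⌊(start+end)/2⌋; the published analyses say
"peak center" without resolving summit vs midpoint, and the summit is
the better estimate of the binding point when a caller provides it.
Bins of `matrix_bin` = 10 bp tile `[anchor − flank, anchor + flank)`
with `flank` = 3000; the bin statistic is the **mean per-base value**
(not the sum), matching common coverage-matrix semantics, and the
peak-center "accumulated signal" is then the sum of bin means over
±500 bp (100 bins). Flanks that run past the covered genome contribute
zeros rather than being truncated, so all rows have equal width; an
exact prefix-integral representation makes the binning agree with a
naive per-base oracle to 1e−9. Metagene summit values are the mean of
the two central bins (the anchor sits on the boundary between them).

## Chromatin-state segmentation

Features for k-means are the concatenated per-mark binned rows after
(1) log1p compression and (2) standardization with a single mean/sd per
mark block. Both choices are deliberate. ChIP signal spans orders of
magnitude; on a linear scale a handful of very tall loci (e.g.
super-enhancer constituents) dominate the Euclidean geometry and k = 2
splits "tall vs rest" instead of "promoter vs enhancer chromatin".
Block-level rather than per-bin scaling is used because a bin that is
non-zero in only one or two peaks has near-zero variance, and dividing
by it turns those few peaks into extreme outliers; one scale per mark
equalizes dynamic ranges across marks without manufacturing outliers
within a mark.

k-means is run with a deterministic initialization: the first center is
a seeded random row, subsequent centers are chosen greedily
farthest-first, and Lloyd iterations (scikit-learn, `n_init=1`) refine
from there. The assignment is therefore bit-stable for a given seed,
including on degenerate all-identical inputs. Cluster naming uses mark
semantics, not cluster order: the cluster with the larger mean
H3K4me3 / (H3K4me1 + ε) peak-center ratio is promoter-like (ε = 1e−9
guards empty-mark division); exact ratio ties leave clusters unlabeled
rather than picking arbitrarily. No sub-classification of weak/poised
vs active enhancers is attempted — the published description of that
split gives no numeric rule.

## Positional annotation

The promoter window is −1000…+100 bp around the TSS, mirrored about the
TSS base on the minus strand (`[tss−99, tss+1001)` in half-open
coordinates) and clipped at zero. Promoter overlap (≥1 bp) takes
priority over distal assignment so the positional scheme partitions the
peak set. Distances are signed anchor−TSS with the sign flipped for
minus-strand genes (negative = upstream of the gene); nearest-TSS ties
break on gene id so annotation is independent of gene-list order.
Percentages are reported to one decimal, the convention used in the
narrative numbers this pipeline reproduces.

## Peak-set overlap

`find_overlaps` builds the bipartite graph of ≥`min_overlap_bp` (default
1 bp; no published gap tolerance) overlaps per chromosome and reports
connected components. The overlapped-peak count is Σ min(|Aᵢ|, |Bᵢ|)
over components — the conservative "min" convention, which is symmetric
and bounded by both input sizes. The component table keeps full
membership, so alternative conventions (merged-interval counts,
per-side membership) remain recomputable. The per-category overlap
report tags peaks with possibly overlapping labels (promoter, enhancer,
super-enhancer), so tag percentages can legitimately sum past 100 —
dual-tagged peaks are a reported feature of this route, unlike the
exclusive positional annotation.

## Super-enhancers

Candidate constituents are H3K27ac peaks that (a) overlap no H3K4me3
peak and (b) lie >2.5 kb (anchor distance) from every TSS. Constituents
are greedily chained when the gap to the growing region is ≤12.5 kb.
Each stitched region's signal is the **sum over constituents** of
input-subtracted RPKM, floored at zero (negative enrichment is noise);
summing per-constituent keeps the score extensive — a cluster of
enhancers outranks a single enhancer of equal density, which is the
point of the rank-ordering approach. For the cutoff, signals are sorted
ascending, rank and signal are rescaled to [0, 1], and the slope is
estimated by central finite differences (one-sided at the ends).
Scanning from the top rank downward, the cutoff is the signal at the
first position whose slope exceeds 1, and every region with signal at
or above the cutoff is super. Plateaus have slope 0 and never trigger
the cutoff; all-equal signals yield zero supers; fewer than two regions
yield all-typical with a logged warning. This estimator is strict: on a
smoothly convex "hockey stick" it calls only the steepest top segment,
which favors specificity over sensitivity in the super set. It is
pinned by an independent brute-force oracle rather than inferred from
any particular tool's code.

## Regulatory integration

DE calling uses the signed linear fold-change convention (−x means a
1/x ratio; no-change is +1): up when fc ≥ +1.5 and padj < 0.05, down
when fc ≤ −1.5 likewise. The fold boundary is inclusive — for
continuous data the choice is immaterial, and inclusivity makes the
rule deterministic at the boundary; the padj comparison is strict.
Quadrants cross the element classes at which the TF binds a gene
(via annotated peaks) with the DE direction; a dual-bound gene counts
once in each element class, so class tallies can exceed the number of
distinct bound DE genes — the dual-bound count is reported explicitly.
Percentages are within-class over up+down; a class with no DE bound
genes reports an absent percentage rather than 0/0.

Occupancy binning uses the knockdown/control score ratio with
symmetric reciprocal thresholds: down ≤ 1/1.2, up ≥ 1.2, stable strictly
within (1/1.1, 1.1). The bands (1/1.2, 1/1.1] and [1.1, 1.2) are
reported as *unclassified* — the three named bins are literally
non-exhaustive, and absorbing the gaps silently would overstate them.
Condition comparisons of (promoter, enhancer) counts use Pearson's
chi-square on the 2×2 table, df = 1, no continuity correction
(`scipy.stats.chi2_contingency`).

## Bliss synergy

Viability is % of untreated control; inhibition is max(0, 1 − v/100)
(super-viability clamps to zero inhibition). The independence
expectation for a combination is e_a + e_b − e_a·e_b from the
single-agent row/column at the same doses; the excess is
(observed − expected)·100 percentage points and the matrix score is the
mean over combination cells only (both doses > 0). Replicate
checkerboards are averaged cell-wise before scoring. Classification:
additive in (−10, 10], synergistic above 10, antagonistic at or below
−10 (the lower tail is named here; the published sentence is silent on
it). Baseline correction and response-surface smoothing offered by
interactive synergy tools are deliberately not reproduced — the score
is the raw Bliss excess. A consequence worth knowing: noise on the
single-agent anchors propagates to whole rows/columns of the excess
matrix, so single-matrix scores scatter with sd ≈ 1.5 points under 3%
viability noise even for truly additive drugs; calibration statements
are therefore made about averages over replicates.

## Synthetic data

The generator emulates the study design, not any real genome: two
chromosomes of 1.4 Mb with one gene per 14-kb slot (200 genes), TSS at
slot+3000, random strands. Gene roles (counts are config defaults):
60 promoter-bound genes planted down on TF knockdown, 50 enhancer-bound
genes planted up, 10 dual-bound genes planted up, 8 bound not-DE, 12
unbound DE, 60 background. TF peaks sit 200 bp upstream of bound TSSs
and at enhancer anchors 6.5 kb downstream of their gene's TSS — past
the 5-kb near-TSS bin yet nearer their own TSS than the neighbor's, so
positional annotation has a well-defined truth. Promoter sites carry
H3K4me3 (amp 40) + H3K27ac (30) + trace H3K4me1; enhancer sites carry
H3K4me1 (35) + H3K27ac (30) + trace H3K4me3. Coverage is a sum of
Gaussian bumps (sd 150 bp, truncated at ±3 sd) in 10-bp bins with
multiplicative log-normal noise, σ = 0.2 per bin — equivalent to ≈2.7%
multiplicative noise on 100-bin peak-center scores, a realistic
replicate-level wobble at which the planted structure is recoverable
but not trivially so. Library sizes are set to the realized coverage
integral so RPKM scaling is self-consistent. The slot width exceeds the
12.5-kb stitch distance so isolated enhancer peaks in adjacent slots do
not chain; super-enhancers are planted structurally at 6 enhancer sites
as three-constituent clusters (±3.5 kb flanks, chosen outside the ±3-kb
matrix window so they cannot leak into the clustering features) with a
1.5× center amplitude.

Knockdown tracks scale the TF bumps by 0.5 (a 50% summit decrease), the
promoter-biased cofactor by 0.95 (5%), and the enhancer-restricted
cofactor per peak by its planted occupancy category (down 1/1.5, stable
1.0, up 1.5 at fractions 1/2, 1/3, 1/6). Histone-mark tracks are
re-noised but unscaled (marks are globally stable in the emulated
design). The DE table plants |fc| = 1.5 + |N(0, 0.8)| with padj
log-uniform in [1e−5, 1e−2] for DE genes and |fc| < 1.2 with padj in
[0.2, 1] for the rest. Dose checkerboards use saturating Hill-type
single-agent responses (Emax 0.45/0.40, EC50 4/3 over doses 0–8) and a
uniform planted Bliss excess per matrix (defaults 0 and 15 points).
All randomness flows from one seed through named per-file-type streams,
so regeneration is byte-identical and adding a file type cannot perturb
existing outputs.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: read-level sampling noise and mappability
artifacts, peak-caller false positives/negatives, overlapping or nested
genes, heavy-tailed peak-width and signal distributions, fractional
cofactor co-occupancy at enhancers, batch effects between conditions,
and dose–response deviations from the Hill form. Recovery rates on this
generator are upper bounds on real-data performance; the value of the
synthetic route is exactness of the planted truth, not realism of the
noise.

## Problem sizes and determinism

The test-suite and acceptance runs use the generator's default scale —
200 genes, ≈140 TF peaks, 20 generator seeds for recovery estimates,
1,000 random instances per brute-force oracle comparison, 200 replicate
checkerboards for Bliss calibration — sizes at which every planted
effect is identifiable and the whole suite runs in seconds. All
stochastic tests are seeded; the pipeline itself is deterministic given
inputs and config, and reports round percentages to one decimal and
scores to two.

## Known limitations

- The super-enhancer cutoff is strict by construction (see above); if a
  more inclusive set is wanted, the ranked table retains all signals so
  any alternative cutoff can be applied downstream.
- `find_overlaps` is quadratic per chromosome in the worst case; fine
  at tens of thousands of peaks, not engineered for millions.
- The minimal GTF reader is not implemented; gene models are consumed
  as the documented TSV.
- Occupancy binning requires a positive control score; peaks silent in
  the control condition must be filtered upstream.
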