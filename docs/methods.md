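# Methods

This note documents the models, conventions and numerical choices behind
`methvar`, and what the synthetic-data generator does and does not emulate.

## Data model and conventions

The unit of measurement is the CpG site: per sample, a methylated read
count m and a total count n, with methylation ratio m/n (undefined, and
kept as missing, when n = 0). Internally all coordinates are 1-based
inclusive, matching methratio-style caller output; BED files are converted
at the I/O boundary (start = bed_start + 1, end = bed_end), and interval
membership is inclusive on both ends. Symmetric CpG dyads are collapsed by
default: a minus-strand record at position p+1 is summed into the
plus-strand record at p, so each CpG site yields one ratio. Whether the
original toolchain merged strands is not knowable from the counts alone;
merging is the default because the analysis treats a CpG site as a single
measurement, and the flag `merge_strands=False` preserves unmerged records.

The bisulfite conversion rate is estimated from non-CpG (CHG/CHH)
cytosines, which are assumed unmethylated in the target species:
rate = 1 − Σm/Σn pooled over sites. Pooling rather than averaging per-site
rates keeps low-coverage sites from dominating the estimate.

## Aggregation

Coverage qualification is joint over an *analysis set*: a site qualifies
only if covered ≥ `min_coverage` (default 5) in every sample of the set,
and a gene's per-sample value is the unweighted mean ratio over its
qualifying CpGs, missing when fewer than `min_sites` (default 5) qualify.
The analysis set is an explicit argument because stratified contrasts (e.g.
a location contrast within one tissue) should qualify sites over exactly
the samples they use; qualifying over a superset is valid but strictly more
conservative (intersection monotonicity). The mean is unweighted — each
qualifying CpG counts equally regardless of depth — because the gene-level
quantity is the average of per-CpG ratios, not a pooled count ratio.

## Selection cascade

Whole-genome discovery keeps genes whose cross-sample variance (n−1
denominator, over non-missing values) strictly exceeds `var_cutoff`
(default 0.006), then removes genes with mean ratio strictly above 0.8 or
strictly below 0.2. The capture-stage core-set filter applies, in order:
n_fraction > 0.5 removal; removal of genes without a computable average
(< 2 non-missing values — coverage qualification is already encoded as
missingness); removal of the bottom decile of variance among the genes
remaining at that point (nearest-rank boundary, k = ⌈q·n⌉, with all ties at
the boundary value removed — conservative and deterministic); and removal
of genes with overall mean < 0.1 or > 0.9. Survivor sets are invariant to
input gene order, and relaxing any threshold yields a superset of
survivors. Every stage is logged with counts and removed identities.

The pipeline runs the core-set filter on all genes by default and gates
discovery behind `run_discovery`: a capture dataset is already restricted
to pre-selected variable genes, and its cross-sample variance scale (set by
counting noise, ≈ p(1−p)/(coverage · n_CpGs) ≈ 3·10⁻⁴ per gene under the
generator's model) is an order of magnitude below a whole-genome biological
cutoff of 0.006. Discovery is a whole-genome-stage operation and is
exercised as such.

## Rank tests and FDR

The Wilcoxon rank-sum statistic is the rank sum W of the first group with
midranks for ties. For tie-free pooled samples with n_x + n_y ≤ 20
(configurable), the p-value is exact: the null distribution of W is built
by a subset-sum dynamic programme over ranks 1..N, and the two-sided p is
twice the smaller tail, capped at 1 (for tie-free data this distribution
depends only on the group sizes). Otherwise a normal approximation is used
with tie-corrected variance n_x·n_y/12·((N+1) − Σ(t³−t)/(N(N−1))) and a
continuity correction of 1/2 toward the mean. Kruskal-Wallis uses the
standard H with midranks and the tie correction 1 − Σ(t³−t)/(N³−N), with p
from χ²_{k−1}; when every pooled value is identical the correction
denominator vanishes and the test returns H = 0, p = 1 flagged degenerate
rather than dividing by zero. With k = 2 and no continuity correction, H
equals the squared Wilcoxon z — kept as a cross-check identity in the
tests, alongside brute-force enumeration oracles.

Benjamini-Hochberg is the plain step-up: q_(i) = min_{j≥i} p_(j)·m/j,
clamped to 1, returned in input order. m counts the genes actually tested;
genes skipped because a group has < 2 non-missing values are reported but
excluded from m. Significance is strict (q < α); α = 1 is treated as "no
filtering" so that the boundary configuration flags every tested gene.

## DMR scanning

The scanner is deliberately simple and transparent rather than model-based:
at each CpG of aligned per-group mean tracks, the signal is the largest
pairwise group difference (max − min); CpGs at or above `min_delta`
(default 0.1) are "above threshold"; maximal runs of above-threshold CpGs
tolerate at most `max_gap` (default 2) consecutive below-threshold CpGs
inside them, and runs with fewer than `min_sites` (default 5)
above-threshold CpGs are dropped. Regions span the first to last
above-threshold CpG, never overlap, and mirror under track reversal. This
run-based scanner is not a reimplementation of smoothing/regression-based
DMR callers and its region counts are not comparable to theirs; it is
meant to localize and display signal, with gene-level inference carried by
the rank tests.

## Ordination and separation

PCA operates on samples × genes with per-gene centering and no scaling
(all features already share the [0,1] methylation scale; scaling is
available by flag), using a full SVD — deterministic up to per-axis sign.
Classical (Torgerson) metric MDS double-centers the squared Euclidean
distance matrix and takes the top-k eigenpairs; for Euclidean input it
reproduces the PCA configuration up to rotation/sign, which the tests check
by Procrustes. Genes with any missing value are dropped before ordination
(no imputation; the count is logged). If all samples coincide, MDS returns
the zero configuration instead of failing on a rank check.

Group separation is the mean silhouette coefficient over samples in the
embedding. When scoring a g-group contrast, the embedding uses k = g − 1
axes: g clusters are separable in at most g − 1 dimensions, and projecting
four location clusters onto two axes superimposes clusters that are
separated in the third. Silhouette makes a visual "the samples separate"
claim quantitative: ≈ 1 for tight distinct clusters, ≈ 0 for no structure.

Enrichment uses the 2×2 Pearson χ² without continuity correction,
N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), with fold enrichment defined as the flag
proportion in the set over the background proportion (infinite when the
background proportion is zero). Expression comparisons use Welch's
unequal-variance t with Welch-Satterthwaite degrees of freedom; two
zero-variance groups with equal means return p = 1 flagged degenerate.

## Synthetic-data generator

The generator emulates the structure of a capture-based bisulfite dataset
over a few hundred pre-selected genes:

- **Gene/CpG layout.** Genes sit sequentially on one synthetic scaffold;
  CpG counts are Poisson(`cpgs_per_gene_mean` = 30) with a floor of 5, and
  spacings are uniform in 10–60 bp.
- **Baselines.** Per-gene baseline methylation is drawn from a three-part
  beta mixture, weights (0.45, 0.20, 0.35) with Beta(0.5, 5), Beta(2, 2),
  Beta(5, 0.5): most genes near 0 or 1, a variably methylated minority in
  between. Draws are clipped to [0.005, 0.995] so logit-scale shifts stay
  defined.
- **Effects.** Fractions `frac_tissue_genes` and `frac_location_genes`
  (defaults 0.10 each) of genes carry an effect: a shift of ±`effect_delta`
  (default 1.0) on the logit scale, applied to a contiguous window of
  `dmr_width` CpGs (default 10, truncated to the gene's CpG count) for the
  affected tissue (across all locations) or the affected location (across
  both tissues) — effects are localized, not gene-wide, with a gene-wide
  mode via `dmr_width` ≥ CpG count. Effect genes draw their baselines from
  the intermediate mixture component: real tissue/location signatures live
  inside the variably methylated, intermediate-level fraction, and an
  effect planted on a ~0/~1 gene would be removed by the level-band filter
  before any test saw it. Null genes have identical true ratios in every
  group.
- **Counts.** Coverage is negative binomial with mean 30 and size 30
  (variance ≈ 2 × mean); the observed success probability is
  p_obs = r + (1 − r)·ε with non-conversion ε = 0.02 (conversion failure
  inflates apparent methylation of unmethylated cytosines; sequencing
  miscalls are not separately modeled); methylated counts are
  Binomial(coverage, p_obs). A configurable number of non-CpG cytosines
  with r = 0 supports the conversion-rate QC.
- **Design.** Two tissues × four locations × 12 samples per cell by
  default, mirroring a hepatopancreas panel of ~12 animals per location
  with a paired muscle panel.
- **Annotation.** ~5% of genes get n_fraction in (0.55, 0.95) (poorly
  assembled sequence), housekeeping flags at 10% background rate with a 2×
  enrichment among effect genes, TE overlap at 10%.

Everything derives from one `numpy.random.default_rng(seed)`: identical
parameters and seed give byte-identical outputs.

**What the generator does not emulate.** There is no per-animal biological
variance component beyond counting noise (null genes vary across samples
only through sampling), no capture-efficiency or bait-design bias, no
read-level artifacts, and no genetic variation (the target setting is
clonal). Consequently, passing recovery tests demonstrates that the
pipeline's inference machinery is correct and calibrated under its stated
sampling model — not that real biological effect sizes of any particular
magnitude are detectable, since real between-animal variance would add to
the denominator of every test.

## Problem sizes

The test-suite simulations use 40–200 genes and 12–96 samples; the
false-discovery control check runs 200 independent null replicates of
200 genes × 48 samples, and the recovery check runs the full default
condition (360 genes, 96 samples). The acceptance script uses the same
default condition plus 100 null replicates. These sizes give Monte-Carlo
standard errors small enough for the stated margins while keeping a full
run in the low minutes on a single core.

## Known limitations

- The DMR scanner thresholds raw group-mean differences; it has no notion
  of coverage-weighted uncertainty at a CpG.
- Missing values are dropped, never imputed, both per-test and before
  ordination; with heavy missingness the ordination gene set can shrink
  substantially (the drop count is logged).
- The Wilcoxon exact path requires tie-free data; heavily tied small
  samples fall back to the tie-corrected normal approximation.
- The pipeline treats groups as unpaired throughout, matching the named
  tests, even where samples from the same animal appear in both tissues.
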