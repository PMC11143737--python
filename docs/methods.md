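# Methods

## Gene-level ASE from allelic counts

ASE is defined as the minor-allele read fraction of a gene in a line:
the alleles with the smaller read count at each heterozygous variant
are assumed to lie on the same haplotype (the silenced X in a clonal-Xi
female line), so per-variant minor counts can be summed without
phasing. The estimator is bounded in [0, 0.5]; 0 is monoallelic, 0.5
balanced. Three filtering rules precede aggregation:

1. variants with ASEReadCounter total depth < 20 reads are dropped;
2. within a gene and line, variants whose consecutive gaps are smaller
   than one read length (100 bp) are chained into clusters, and only
   the deepest variant of each cluster is kept (ties broken toward the
   smaller position), so a read spanning two variants is not counted
   twice. Chaining (single linkage on consecutive gaps) is the minimal
   reading of the collapse rule; a greedy in-order alternative is
   available via `collapse_method="greedy"`;
3. the ASE denominator is ref + alt, not the ASEReadCounter
   `totalCount`, so ASE is a two-allele fraction; the depth filter is
   applied to `totalCount` as stated above.

Bi-allelic expression is tested per gene × line with the one-sided
exact binomial upper tail against p₀ = 0.1 and called at BH *q* < 0.01.
The BH family is all X-chromosome gene × line tests of a cohort run
jointly (a per-line family is available via `bh_family="per-line"`);
autosomal records keep raw p-values. XIST clonality uses the one-sided
lower tail against p₀ = 0.05 at α = 0.05. Because the input is not
SNP-aware-realigned, the pooled reference-allele read fraction is
reported as a QC diagnostic rather than corrected.

XIST itself is excluded from per-line ASE summaries by default
(`include_xist=True` restores it): its expression comes from the
inactive X and would otherwise distort line-level erosion summaries.

## Line staging

Each female line is summarized by (XIST log₂(CPM + 0.5), fraction of
informative X genes called bi-allelic). Lines below 1.5 log₂CPM of
XIST are "low-XIST" (strict `<`). Features are z-scored over female
lines only, and k-means (50 restarts, fixed seed, scikit-learn) is run
at k = 3; the cluster count is checked with the Tibshirani gap
statistic using B = 100 uniform reference draws over the feature
bounding box and the rule "smallest k with Gap(k) ≥ Gap(k+1) −
SE(k+1)". Cluster indices are relabeled deterministically by
phenotype: group 3 has the lowest mean XIST, group 1 the lowest
fraction bi-allelic of the remainder, group 2 the rest; the labeling is
invariant to input row order.

The erosion trajectory is described two ways: a LOWESS curve
(statsmodels, default span 2/3) of the bi-allelic fraction on XIST
expression, and a three-parameter decreasing logistic
`A / (1 + exp(b (x − x₀)))` of mean ASE on XIST expression fitted by
least squares with multi-start initialization over a grid of
inflection points and rates (A bounded by 0.5, the ASE maximum). The
reported "slope" is −b, sign-matched to a decreasing curve. A
near-constant response is flagged unidentifiable instead of fitted.
Both fits use all female lines with ≥ 10 informative genes.

## Escape classification

Eligible genes need ≥ 10 informative lines in both the low- and
high-XIST groups. Classes: *biallelic* if bi-allelic in > 80% of
informative lines (strict), *monoallelic* if in none, else *variably
biallelic*. Per gene, enrichment of bi-allelic lines in the low-XIST
group is tested with a one-sided Fisher exact test and the ASE shift
with a one-sided Wilcoxon rank-sum test (exact when both groups have
n ≤ 50 and no ties, tie-corrected normal otherwise); per-gene tests
are reported unadjusted at p < 0.05, which mirrors the screening
character of the analysis — a multiplicity caveat applies to any
genome-wide reading. Category comparisons against human tissue escape
status exclude XIST and PAR genes.

## Differential expression

Genes with fewer than 10 total counts are removed. TMM factors are
computed with the canonical parameters: reference sample by
upper-quartile closeness to the mean, 30% two-sided trim on M-values,
5% on A-values, inverse delta-method precision weights, factors
normalized to geometric mean 1 (cross-checked against the edgeR
reference implementation in the test suite). Expression is
log₂(CPM + 0.5) on TMM-effective library sizes.

The two-group test deliberately replaces a donor-aware mixed model
with a simpler fixed-effects analysis: replicate lines of one donor
are averaged (removing within-donor correlation), then a per-gene
Welch t-test with BH correction is applied. This preserves the
contrast structure and is fully reproducible and dependency-free;
numbers from a mixed-model analysis of real data are not expected to
match exactly. Genes with zero variance in both groups are flagged NA
and excluded from the BH family.

The disease-gene screen keeps significant genes (q < 0.05) whose 95%
normal CI of |log₂FC| covers log₂(1.5) — i.e. whose fold change is
consistent with the 50% expression change that could mask a
heterozygous loss-of-function effect — or whose point estimate already
exceeds it. The screen is monotone in the standard error.

## Enrichment

Annotation intervals (1-based closed internally; BED converted at the
boundary) map to genes via symmetric strand-independent windows around
the strand-aware TSS: ±1500 bp for methylation probes, ±3000 bp plus
the full gene span for histone-mark peaks. The gene body is the full
start–end span; exon-level resolution would not change the gene-set
outcome for contiguous spans. Overlap is closed-interval overlap, so a
single shared base pair counts.

Over- and under-representation use the hypergeometric distribution
over the universe of genes analyzed in the corresponding DE contrast
(post low-count filter); DE lists are split by direction before
testing. Effect size is the relative enrichment
`(overlap/annotation) / (DE/universe)`, whose null expectation is 1;
B = 1000 random same-sized gene sets drawn without replacement give a
permutation distribution and the observed RE's upper-tail quantile.

## Synthetic cohorts

The generator emulates the *derived* tables of a clonal-Xi iPSC ASE
study, not raw reads. Per female line a latent erosion level *e* is
drawn uniformly from its group's range — defaults (0, 0.1),
(0.25, 0.5), (0.45, 0.8) for groups 1–3, overlapping deliberately so
that staging is a statistical, not a trivial, problem. XIST log₂CPM
follows a decreasing logistic in *e* (maximum 10, inflection at
e = 0.40, steepness 14, Gaussian noise SD 0.4), placing group 1 near
10 log₂CPM, group 2 in an "appreciable" mid-range, and group 3 mostly
under the 1.5 threshold, as in the erosion-stage geometry the pipeline
assumes. Each X gene has a class with a baseline Xi fraction f_g (PAR
fixed at 0.5; escape ~ Beta(4,16), mean 0.2; variable ~ Beta(2,30);
inactive 0) and a susceptibility s (0 / 0.5 / 0.5 / 0.2), giving
f_gl = min(0.5, f_g + s·e). Variant depth is zero-truncated negative
binomial (mean 80, size 5), minor reads binomial in f_gl, and the
minor haplotype lands on ref or alt with equal probability (unphased
input); an optional `ref_bias` tilts read probabilities toward the
reference, and `exact_fractions` is an infinite-depth switch for
degenerate tests. Expression counts are negative binomial (size 10)
with X dosage 1 + f_gl in females, planted sex-biased autosomal
effects (|log₂FC| 0.5 and 1.0), and an XIST-bound autosomal gene set
with a male-biased effect of 0.3·(1 − e) log₂FC that decays with
erosion. Annotation sets are constructed consistently with the truth:
five disjoint methylation "transition" gene sets ordered from
erosion-prone to erosion-resistant genes, histone peaks at the
promoters of de-repressible genes, and the XIST-bound set itself.

Cohort sizes default to the study design the pipeline targets (117
males, 74/45/46 females per group); gene counts (120 X genes plus
XIST, 400 autosomal) are scaled to desk size so a full synthetic run
completes in seconds. What the simulator does **not** model: per-cell
heterogeneity within a culture (erosion is a culture average — bulk
ASE cannot distinguish uniform partial de-repression from a mixed
population), linkage/haplotype structure, mapping artifacts beyond a
uniform reference bias, and library-preparation covariates. Passing
tests therefore demonstrate the statistical machinery under the
model's assumptions, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

- Exact binomial/hypergeometric tails via scipy; the test suite checks
  them against rational-arithmetic enumeration on all small instances.
- Fisher and Wilcoxon tests are exact where feasible (documented
  approximations otherwise) for reproducible small-sample p-values.
- Collapse ties break toward the smaller position; BH over an empty
  family is a no-op; zero-margin Fisher tables return p = 1; lines
  with no informative genes get NA summaries and are excluded from
  staging; a degenerate all-identical feature matrix raises rather
  than returning arbitrary clusters.
- Missing values serialize as `NA`; floats are written with 6
  significant digits and round-trip through the readers at that
  precision.
- All randomness flows through `numpy.random.default_rng` seeds; fixed
  seeds give bit-identical cohorts and pipeline outputs.

## Known limitations

- The fixed-effects DE stand-in underuses replicate structure relative
  to a mixed model; its q-values are calibrated under independence
  (verified by simulation) but real donor effects may inflate them.
- The gap statistic on the default cohort sits near its decision
  boundary: the erosion continuum between groups 2 and 3 means the
  chosen k is 3 at most seeds but can exceed 3, and ~5% of female
  lines are inherently ambiguous between those groups, capping
  truth-recovery of any staging method at roughly 95%.
- Beta-binomial overdispersion of allelic counts, haplotype-aware ASE
  and phasing are out of scope.
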