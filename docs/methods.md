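# Methods

## The aggregation test

**Statistic.** For a set of families with subtype-labeled tumors, the
concordance statistic `S` counts the families containing at least two
tumors with an identical subtype label. The definition is deliberately
binary per family: a three-tumor family contributes 1 whether two or all
three members agree. Families with a single tumor can never contribute.

**Null model.** Under the null, subtype labels carry no family signal, so
the observed label multiset is exchangeable across samples. The null
distribution of `S` is obtained by re-partitioning the multiset uniformly
at random into the observed family sizes. Two implementations:

* `permutation_null` — vectorized Monte Carlo (default 100,000 replicates,
  seeded, reproducible). A replicate permutes the encoded label vector and
  checks each family block for a duplicated label via a within-block sort.
* `exact_null` — exact enumeration by a memoized recursion over families:
  for each family the multiset of labels it receives is enumerated with its
  integer arrangement count, and the residual label counts recurse.
  Arrangement counts are exact integers; masses are exact up to one final
  float division. Instances above a configurable budget (default 10^7
  distinct arrangements) are refused with a pointer to Monte Carlo. The
  exact null is the oracle against which the sampler is tested (agreement
  within 3 binomial standard errors at 100k replicates).

**P-value.** Plain proportion of null mass at `S* >= S_obs`. The
`(r+1)/(n+1)` convention is available behind a flag (Monte-Carlo nulls
only) and is never the default.

**Pool policy.** `multicase_only` (default) permutes only the samples of
families with ≥ 2 tumors. This is the only construction computable from a
published per-family subtype table of multi-case families, and it
reproduces both bundled tables' reported significance levels; singleton
families are provably irrelevant to `S` itself under either policy.
`all_samples` (permute every sample over every family) is implemented for
completeness.

**Conservativeness.** `S` is integer-valued on a handful of multicase
families, so the achievable test sizes are a coarse grid: for the
discovery-style pool (ten pairs and one trio) the null tail jumps from
≈ 0.059 at `S >= 6` to ≈ 0.012 at `S >= 7`. A nominal-0.05 decision rule
therefore realizes a true type-I error well below 0.05 (≈ 0.02 in our
simulations at the default cohort design). This is intrinsic to discrete
permutation tests, not a defect of the sampler; the test is valid
(never anti-conservative) but conservative, and power statements should be
read accordingly.

## Subtype classification

Nearest-centroid assignment: the sample's expression profile is correlated
with each subtype centroid over their shared genes and assigned the
argmax. Rank-based (Spearman) correlation is the default, matching the
convention of the standard 50-gene intrinsic-subtype classifier; Pearson is
a config option. Gene matching requires a configurable minimum overlap
(default 50% of centroid genes) and fails loudly, naming missing genes.
Ties are broken by centroid column order — the declared subtype order in
the centroid file is part of the classifier. Zero-variance profiles are an
error (rank correlation undefined) with an actionable message. No gene-wise
scaling is applied before correlation by default; correlation is already
location/scale-invariant per sample, and rank correlation additionally
invariant to monotone transforms. When an expression file carries several
probes per gene symbol, the most variant probe is kept at load.

Percentages in distribution tables are rounded half away from zero to
integer percent (e.g. 33/70 → 47%). Enrichment between two groups uses the
two-sided Fisher exact test on the 2×2 (subtype vs not) × (group A vs B)
table.

## BRCA-likeness signatures

A signature model is pure data: an ordered gene list, one weight per gene,
an intercept, the class-label pair, and the subtype it applies to. Scoring
is the plain linear rule `w·x + b`; a strictly positive score is BRCA-like,
a score of exactly zero is conservatively called sporadic-like. Only
samples whose assigned subtype matches the model's `applicable_subtype`
are scored — basal-restricted and lumB-restricted signatures never see
other samples. Published signature weight sets load from the signature CSV
format; `train_signature_model` fits a soft-margin linear SVM (C default 1)
for synthetic experiments, z-scoring genes with training statistics and
folding the scaling into the stored weights so the saved model needs no
preprocessing state. Training is deterministic up to the SVM solver's
convergence tolerance (tightened to 1e-6). No probability calibration is
attempted; margins only.

## Methylation calls

A per-probe MS-MLPA ratio strictly greater than 0.2 is a positive
promoter-methylation call; input ratios are assumed kit-normalized and must
be nonnegative. A sample is promoter-positive for a gene if **any** of its
probes for that promoter is positive (the published analyses report
gene-level positivity without stating the aggregation rule; any-probe is
our documented choice). The expression association is a two-sided
two-sample t-test of the silenced gene's expression, methylated vs
unmethylated samples; Welch's unequal-variance form is the default because
the compared groups are typically very unbalanced (a handful of methylated
tumors vs hundreds), with the pooled variant behind a flag. Note the Welch
effective degrees of freedom are bounded by the small group, which caps the
attainable significance when only ~6 samples are methylated.

## Unsupervised structure

Pipeline order is fixed and asserted by tests: select the `k` most variant
genes on **raw** values (standardizing first would equalize all variances),
then standardize each selected gene to zero mean and unit variance (sample
variance, ddof=1), then cluster samples agglomeratively — Euclidean metric,
complete linkage by default, `k = 500` for a whole-cohort view and 200 for
a restricted one. Variance ties at the cutoff keep the lexicographically
first gene id. Dendrograms serialize to Newick with merge heights so trees
are diffable text; gene-wise (two-dimensional) clustering is not performed
by default.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, sized like the
motivating study design:

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` / `n_markers_per_subtype` | 200 / 10 | marker blocks per subtype plus background genes |
| `prevalence` | (.13, .10, .47, .26, .04) | subtype frequencies (basal, HER2, lumA, lumB, normal) as observed in familial non-BRCA1/2 tumors |
| `delta` | 2.0 | marker shift (log2 units) of a subtype's markers in its own centroid |
| `sigma` | 1.0 | per-gene Gaussian noise sd on the log scale |
| `family_sizes` | 47×1, 10×2, 1×3 | a 58-family cohort contributing 70 tumors |
| `rho` | 0.0 | probability a member inherits the family founder's subtype |
| `methylated_fraction` | 0.06 | promoter-methylation prevalence (≈ the observed BRCA1-promoter positivity rate) |
| `methylation_knockdown` | 2.0 | expression decrement of the silenced gene |

`delta = 2, sigma = 1` are conventions — the separability of subtypes on
any given platform is not something the published tables constrain — chosen
so that classification is accurate but not trivial; at `sigma = 0.5` the
classifier recovers ≥ 99% of labels. The founder-inheritance mixture for
`rho` is the simplest mechanism interpolating between the exchangeable null
(`rho = 0`, where the cohort's statistic provably follows the permutation
null) and perfect aggregation (`rho = 1`, where every multi-case family is
concordant); it is a modeling convention, not an empirical claim.
Methylation ratio ranges (0.3–0.8 vs 0.0–0.1) straddle the 0.2 threshold
unambiguously, so synthetic truth and threshold calls coincide by
construction. Noise is independent Gaussian per gene: no probe-level
artifacts, batch effects, copy-number structure, or gene–gene correlation
beyond the subtype blocks. Passing recovery tests therefore demonstrates
correctness of the machinery, not classifier performance on real arrays.

Randomness: one master seed; each stage (centroids, labels, noise,
methylation) draws from a stream spawned with a fixed per-stage key, so
enabling methylation does not perturb the expression draws.

## Problem sizes used in the test suite

Calibration and power properties are estimated over 1,000 simulated
cohorts per condition with 2,000-replicate nulls (the full 100,000
replicates are reserved for the headline p-values, where Monte-Carlo error
matters); the null-embedding goodness-of-fit uses 4,000 small cohorts
conditioned on the modal label multiset. These sizes give binomial
standard errors a factor ~5 below the effects being asserted.

## Known limitations

* The test conditions on observed family sizes and the label multiset; it
  does not model ascertainment, penetrance, or covariates, and provides no
  heritability estimate.
* Discreteness makes the test conservative at conventional levels for
  small family counts (see above); exact enumeration does not remove this,
  it only removes Monte-Carlo error.
* Real 50-gene centroids and published signature weight sets are user-
  supplied data; the package ships only synthetic stand-ins generated at
  run time, and cohort-level results that depend on the original microarray
  data are out of scope.
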