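# Methods

This note documents the statistical procedure lrprop implements, the
choices that were genuinely open when it was built, the numerical
conventions, and what the synthetic-data generator does and does not
emulate.

## The model

The data are an N × D table of non-negative integer counts (samples as
rows). Counts from sequencing assays are treated as *compositional*: only
the ratios between features within a sample carry information, because the
per-sample total is set by the instrument, not the biology. The analysis
therefore never interprets raw count differences; every statistic is built
on within-sample log-ratios.

Each sample vector *x* is transformed by either

* **clr** — ln(x_i / g(x)), with g(x) the geometric mean of the sample over
  *all* D features. Every clr row sums to zero; the transform is invariant
  to rescaling a sample by any positive constant.
* **alr** — ln(x_i / x_ref) against a user-designated reference feature,
  with the reference's (identically zero) self-ratio column dropped. When
  several reference features are named, the denominator is their geometric
  mean. If the reference is genuinely constant in absolute terms (a
  spike-in, a trusted housekeeping gene), alr recovers absolute abundances
  from relative data up to a constant, and proportionality computed on alr
  data equals the absolute-data analysis — this is tested.

For two transformed columns A_i, A_j, association is measured through the
log-ratio variance VLR = var(A_i − A_j) and its three scalings phi, rho and
phi_s (see README for definitions). rho and phi_s are deterministically
linked by rho = (1 − phi_s)/(1 + phi_s); the package computes both
independently and the test suite asserts the identity to 1e-10.

Key invariances, all under test:

* **Closure**: clr (hence VLR, and all three metrics) is identical on
  absolute counts and on their row-normalised relative version.
* **Filtering**: the low-count filter ("at least `min_count` counts in at
  least `min_samples` samples", default 10/10, evaluated on the raw counts)
  is applied *after* the clr geometric means are taken over all features.
  Retained entries of the metric matrix are therefore bit-identical to the
  corresponding entries of the unfiltered matrix; filtering subsets the
  result, it never alters it. For alr the transform depends only on the
  reference, which must itself pass the filter — silently dropping the
  denominator would change the analysis, so it is an error.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `zero_replacement` | 1 | value substituted for zero counts before logs (multiplicative replacement). Counts are unitless; 1 is the smallest observable non-zero count. Exposed so analysts can probe sensitivity — with many zeros the choice can dominate results. |
| `filter` | none (CLI: 10, 10) | low-count feature filter, counts × samples. |
| `cutoff` | 0.95 | pair-extraction threshold on rho ("highly proportional"). There is no hypothesis-testing framework for proportionality; the cutoff is a practical screening device, not an error rate. |
| `linkage` | complete | agglomerative linkage for co-clustering (see below). |
| `k` / `height` | user-supplied | dendrogram cut; no default is imposed because the right granularity is data-dependent. |

## Module discovery

The symmetric metric matrix is turned into a distance — 1 − |rho|, or phi_s
used directly — and clustered agglomeratively; two features are
*co-clustered* if they share a branch after cutting the dendrogram. Under
the modulus, perfectly anti-proportional pairs sit at distance zero and
co-cluster with proportional ones. Cluster indices are assigned in
decreasing size order (ties broken by the lowest member index), so
"co-cluster 1" is reproducibly the largest cluster, and the partition is
equivariant under feature permutation.

**Linkage choice.** Complete linkage is the default. On 1 − |rho| distances
the diffuse background sits at mutual distances near 1 while a tight
proportional module sits near 0 — but, through the shared clr geometric
mean, a loud module is *closer to every background feature than background
features are to each other*. Under average linkage a module therefore acts
as a nucleus and absorbs the background one feature at a time, destroying
the module structure at any reasonable cut. Complete linkage scores a
candidate merge by the cluster diameter it would create, which blocks
exactly this absorption; on planted-module data it recovers the modules
cleanly where average linkage does not.

**Prioritization.** Candidate modules are ranked by the two variance axes of
their highly proportional pairs: VLR (tightness of proportionality, lower
is better) and VLS = var(A_i) + var(A_j) (how loudly the pair's features
vary, higher is better; for rho, VLR/VLS = 1 − rho identically). Clusters
are ranked by median VLS, descending, over their within-cluster passing
pairs: among equally tight modules, the one whose members swing most across
samples is the best candidate for condition-driven change. The high VLS may
of course reflect batch effects rather than condition; the log-ratio PCA
view exists to check whether sample groups actually separate on the module.

## The simulation bench

`simulate_absolute` draws an "absolute" count matrix where ground truth is
known, and `close_to_relative` divides each row by its total — producing the
relative data a sequencer would report. Five measures are then scored
against the Pearson correlation of the absolute log counts on a seeded
random sample of feature pairs (default 10,000): correlation of relative
data, correlation of clr data, rho, f(phi), f(phi_s), where
f(x) = 1 − 2·logistic(ln x) = (1 − x)/(1 + x) maps the dissimilarities onto
the correlation range with f(phi_s) = rho exactly. A pair is counted as a
*spurious event* for a measure when the measure claims a strong association
(|m| ≥ 0.7) while the absolute correlation is negligible (|r| ≤ 0.3); both
thresholds are configurable, and the modulus convention means a strong
anti-association claim also counts as a claim.

Generator defaults, chosen once as the study conditions:

* 1,000 background features, NB with means log-uniform in [10, 1000] and
  dispersions uniform in [0.1, 0.5] (variance m + αm²) — spanning
  lowly- to highly-expressed transcripts with realistic bulk RNA-Seq
  overdispersion — plus one non-random feature, over 30 samples.
* The **non-random feature**'s expected abundance ramps linearly across the
  sample order from 0.1× to 10× the summed background means — a 100-fold
  monotone swing, as for a hyper-induced transcript over a time course.
  Because this feature comes to dominate the library, closure divides every
  other feature by a systematically trending denominator; this is the
  mechanism that manufactures spurious relative correlations while leaving
  the absolute data independent.
* 10 proportional pairs planted among the background features (ratio drawn
  from [2, 5], lognormal jitter σ = 0.05) so that the "high proportionality
  predicts high absolute correlation" property can be scored on known
  positives.
* All correlations in the bench are computed on the log scale, the scale
  every competing measure operates on; zeros are replaced by 1 before
  closure so both pipelines see the same strictly positive data.

What the generator does **not** emulate: GC/length biases, sample-specific
protocol effects, correlated background modules, zero inflation beyond what
the NB produces, and discreteness effects of very small counts. Passing the
bench therefore shows that the metrics behave as the theory predicts under
library-size confounding — not that they are robust to every artifact of
real sequencing data. The same report pipeline runs unchanged on any
user-supplied absolute count matrix.

`simulate_modules` is the second fixture generator: each planted module
shares one latent lognormal trajectory (loudness = the latent log-sd) and
members track it up to a feature-specific constant and lognormal jitter, on
an independent NB background. It exists to give module discovery a ground
truth where both membership and loudness ordering are known.

## Numerical conventions

* Natural logarithms throughout; the metrics are ratios of variances, so
  the base cancels anyway. Geometric means are computed as exp(mean(ln x)).
* Sample variances use the unbiased N − 1 denominator. The metrics are
  invariant to this choice; reported per-feature variances and VLS are not,
  so the convention is fixed here.
* The pairwise pass computes var_i + var_j ± 2 cov_ij from one covariance
  sweep, streamed over feature-column blocks so scratch memory beyond the
  M × M result stays at O(M · block). The contraction uses a fixed-order
  kernel (einsum, not BLAS gemm) on C-ordered data: per-entry summation
  order is then independent of blocking and of which other columns are
  present, making the blocked path bit-identical to the one-shot path and
  the filtered computation bit-identical to subsetting. BLAS gemm does not
  have this property (its rounding depends on operand shape); the speed
  cost at desk scale is negligible.
* var_i + var_j − 2 cov_ij cancels catastrophically for near-proportional
  pairs; any VLR below 1e-12 × (var_i + var_j) is numerically
  indistinguishable from exact proportionality and is snapped to 0 (after
  clipping negatives), so constructed proportional pairs report VLR = 0 and
  rho = 1 exactly. rho is clipped to [−1, 1] for the same reason at the
  other end. The same relative floor flags the phi_s denominator
  var(A_i + A_j) as degenerate: exactly anti-proportional pairs are
  reported as NaN, never ±inf, so clustering cannot silently absorb them
  (in distances they are mapped to the maximum observed distance).
* phi's asymmetry is preserved in the matrix; pair extraction symmetrizes
  by taking the smaller of the two orientations (a pair passes if either
  does). The evaluation bench reads phi in the sampled i < j orientation.
* PCA centres columns but does not rescale them (clr data already share a
  log scale); component signs are fixed so the largest-magnitude loading is
  positive, making scores reproducible across linear-algebra backends.

## Problem sizes

The test suite and the acceptance script run at desk scale: metric fixtures
up to 100 samples × 500 features, oracle (naive per-pair loop) comparisons
up to 20 × 15, the evaluation bench at 1,001 features × 30 samples with
10,000 sampled pairs, module recovery at 50 features × 20 samples. These
sizes exercise every code path, including the blocked streaming path, while
keeping the whole suite in seconds.

## Known limitations

* clr-based proportionality changes when features are added or removed from
  the dataset (the geometric mean moves); only alr against a truly fixed
  reference is immune. clr errors tend toward false negatives.
* Zero replacement is the crudest defensible strategy; results with many
  zeros should be checked for sensitivity to the replacement value.
* There is no hypothesis-testing framework; cutoffs are screening devices.
* Counts are "count-compositional": at very small counts the discreteness
  of the data and the zero-replacement choice dominate the log-ratios. The
  default 10-counts-in-10-samples filter exists to keep such features out.
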