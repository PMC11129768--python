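# Methods

`rankgsea` scores single cells against signature gene sets using only each
cell's *within-cell expression ranks*, tests the scores for per-cluster
enrichment, and aggregates the per-method verdicts into one robust call per
gene set per cluster. This note documents the statistical models, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic benchmark does and does not demonstrate.

## Why ranks

A score that depends only on the ordering of a cell's own expression values
is invariant to any per-cell monotone transform (library-size scaling,
log-transformation) and to cohort composition: adding or removing cells
cannot change an existing cell's score. Both properties are enforced by
test, the second at bit level — a cell scored alone, in a shuffled cohort,
or in an augmented cohort produces the identical float64 result. Achieving
bitwise (not merely approximate) equality required care: numpy's pairwise
summation rounds differently over strided and contiguous axes, so the
ssGSEA running sum and the Viper quantile mean are reduced along contiguous
per-cell memory.

## Ranking conventions

Ranks are computed per cell; `rank_desc` gives 1 to the highest value,
`rank_asc` to the lowest. Ties default to the *average* policy —
deterministic and standard for Mann–Whitney-type statistics; `min`, `dense`
and a seeded `random` policy (reproducible from the seed and the cell id,
never from column position) are available. Zeros (dropouts) are ranked, not
dropped: they form one tie group at the least-expressed end, which is what
lets JASMINE's "rank among expressed genes" reuse the full-vector ranks
unchanged. An all-zero cell gets all-tied ranks and near-null scores rather
than an error.

## The six scores

Let a cell have `n` genes, a set `S` have `n_s` members, and `r(g)` be a
gene's descending rank.

**AUCell-style.** `L = ceil(f · n)` with top fraction `f = 0.05`. The
recovery curve `H(x) = #{g ∈ S : r(g) ≤ x}` is summed over depths
`x = 1..L` and divided by its maximum attainable value
`Σ_x min(x, n_s)`, so the score sits in [0, 1] with 1 meaning the set
packs the top of the cell's ranking. The normalisation choice (divide by
the perfect-packing maximum) pins the interpretation; the raw AUC alone is
scale-dependent in `L` and `n_s`.

**UCell-style.** Ranks are capped at `r_max + 1` with `r_max = 1500` to
discount the uninformative dropout tail, then
`U = Σ_{g∈S} min(r(g), r_max+1) − n_s(n_s+1)/2` and
`score = max(0, 1 − U/(n_s · r_max))`. The floor at 0 only binds when
`n_s` approaches `r_max`; clamping is logged.

**singscore-style.** The mean ascending rank of the set genes, min–max
normalised by its extreme values `(n_s+1)/2` and `(2n−n_s+1)/2`; a set
equal to the whole genome is rejected (zero denominator).

**ssGSEA-style.** Genes are ordered per cell by descending expression
(ties broken by gene order, deterministically). At list position `i` the
weight is the rank value `(n−i+1)^α` with `α = 0.25`; the enrichment score
is the *sum* over all positions of the gap between the weighted in-set CDF
and the uniform out-of-set CDF (the integral form of single-sample GSEA).
No across-cell range normalisation is applied — deliberately, so that each
cell's score is cohort-independent.

**JASMINE-style.** Two components per cell: (i) the mean descending rank
of the expressed set genes divided by the number of expressed genes (0.5,
the null value, when no set gene is expressed — logged); (ii) the odds
ratio of the detection contingency table (set vs background × expressed vs
not), with a Haldane correction of +0.5 on all four cells whenever any
count is zero, keeping the ratio finite. Both components are min–max
scaled across the scored cells ((1 − rank-mean) and OR separately) and
averaged. The final scaling makes the *final* JASMINE score
cohort-dependent — an inherent property of the construction, in tension
with the cohort-independence of the other five; `jasmine_components`
exposes the unscaled, cohort-independent parts, and the tests assert
independence on those. When a component has zero spread across cells its
scaled value is set to the neutral 0.5. A likelihood-ratio variant of the
enrichment component is available behind `jasmine_enrichment`.

**Viper-style (aREA).** Each ascending rank maps to the interior quantile
`(rank − 0.5)/n` (strictly inside (0,1)) and through the standard-normal
quantile function Φ⁻¹; the set score is the mean over members times
`sqrt(n_s)` — a normalised enrichment score with null mean ≈ 0 and
variance ≈ 1. Ranks are computed *within* each cell: only that reading is
consistent with cohort independence, which the package treats as the
defining property of the method family. With unsigned gene sets (every
member mode +1, weight 1) the three-tailed aREA combination reduces
algebraically to this two-tailed term; signed-regulon modes are out of
scope and the implementation is documented as that degenerate case.

## Differential testing

For each scoring method and cluster, every set's per-cell scores in the
cluster are compared against all other cells (one-vs-rest) with the
two-sided Wilcoxon rank-sum test: exact enumeration when the combined
sample is ≤ 25 and tie-free, otherwise the normal approximation with tie
and continuity corrections. A combined sample of identical values returns
p = 1 exactly. P-values are Bonferroni-multiplied by the number of sets
tested within each (method, cluster) — per-cluster marker-test semantics —
and a set is significant at adjusted p ≤ 0.05. Direction is `up` when the
cluster mean exceeds the rest; a zero difference resolves to `up` and is
logged. No minimum-effect-size prefilter is applied.

## Robust rank aggregation

Per cluster and direction, each method contributes its significant sets
ordered by p (ties: |effect| descending, then name). Each set's k
normalised ranks, sorted ascending, are compared with uniform order
statistics through the binomial upper tail
`β_{x,k}(r_(x)) = Σ_{ℓ=x..k} C(k,ℓ) r_(x)^ℓ (1−r_(x))^{k−ℓ}`;
`ρ = min_x β_x`, and the reported p-value is `min(1, ρ·k)` (Bonferroni
over the k order statistics). Methods with empty lists still count toward
k; a set listed by nobody aggregates to p = 1.

Two normalisation dialects are provided and recorded in every output
header. The default, `union`, divides ranks by N = the number of
*candidate* sets (all sets tested for the cluster), imputing rank N for
sets a method did not list — the standard full-list normalisation, and the
only one that behaves sensibly when significant lists are short: a lone
unanimous top set then gets `r = 1/N` everywhere and a tiny ρ. The
alternative `paper` dialect divides each set's ranks by that set's own
largest rank across methods (after the same imputation); read literally
this forces the worst-ranking method's entry to exactly 1 for every set,
so a set unanimously ranked first normalises to all-ones and can never
reach significance. The dialect is kept for comparability, its degeneracy
is documented, and the corresponding cross-dialect agreement check in the
acceptance suite fails by design of the formula — a known, intended
divergence, not a bug. Calibration under the null is conservative for the
default dialect (measured significant fraction ≈ 0.024 at nominal 0.05
with k = 6, N = 50).

The correction factor is k, the number of methods; an additional
across-sets correction is not applied (the per-method p-values entering
the ranking were already Bonferroni-adjusted). Up and down directions are
aggregated separately.

## Method concordance

Agreement between methods is summarised by Kendall's coefficient of
concordance computed pairwise (m = 2 raters): for each method pair and
each gene set, the two per-cell score vectors are ranked and
`W = 12·S / (m²(n³−n) − m·T)` with S the squared deviations of rank sums
and T the tie correction. W is 1 for identical orderings, ~0.5 for
independent ones (two-rater null) and 0 for exact reversal; both vectors
constant gives an undefined (missing) W. Pair medians across sets and an
overall median summarise the report. Whether concordance should be taken
over cells per set, over sets per cell, or on cluster summaries is a
genuinely open design choice; the per-set-over-cells reading is used and
recorded in the report.

## Synthetic benchmark

The generator emulates a clustered droplet-style experiment scored against
a hallmark-like collection: gene baseline means are log-normal(0.5, 1);
counts are negative-binomial with `var = μ + μ²·φ`, `φ = 0.3` (dropout
zeros arise naturally; no extra zero-inflation layer); 3 clusters × 200
cells over 2000 genes; 20 mutually disjoint sets of 30 genes; 3 planted
sets whose members' means are multiplied 4-fold in exactly one target
cluster each. These defaults are the package's benchmark condition
throughout the tests and the acceptance script; module-level tests use the
same generator at smaller sizes where only mechanics are exercised.

What passing the benchmark shows: the full pipeline recovers strong,
internally consistent planted signal at realistic sparsity, with zero
up-direction false positives among the 17 null sets and a null
(no-signal) type-I fraction far below 0.05. What it does not show:
performance on real data with library-size variation, batch effects,
correlated gene programs, overlapping sets, or subtle effect sizes — none
of which the generator emulates. The high median Kendall's W (~0.94) on
the benchmark reflects the strength of the planted signal, not the
agreement one should expect between methods on real tissue.

One secondary effect of planting is worth knowing: upregulating 30 genes
in cluster A depresses every other gene's rank slightly in A and depresses
the planted set's scores relative to the rest in clusters B and C, so the
planted sets legitimately appear as *down*-significant in non-target
clusters. False positives are therefore counted in the planted (up)
direction.

## Numerical choices and degenerate inputs

- Ties: average everywhere by default; ssGSEA's descending order breaks
  exact ties by gene position (stable sort), so scores remain monotone-
  transform invariant even with ties.
- Quantiles `(rank − 0.5)/n` keep Φ⁻¹ finite for every rank including the
  extremes.
- Exact Wilcoxon mode refuses tied data; `auto` falls back to the corrected
  normal approximation.
- All-zero genes can be filtered (`filter_zero_genes`, idempotent; erroring
  only if nothing survives); all-zero cells are retained with a warning.
- Gene-set restriction keeps sets with 5–500 members after intersection
  with the matrix (configurable; bounds are a package default, logged).
- Gene identifiers match by exact case-sensitive string equality; no ID
  conversion is attempted.
- Every randomised component (simulation, random tie policy) is driven by
  an explicit integer seed; identical configuration implies bit-identical
  output.

## Problem sizes used by the checks

The acceptance script and the end-to-end tests run the default benchmark
(600 cells × 2000 genes), 20 null replicates of the same size for type-I
measurement, 10⁵ Monte-Carlo draws per order-statistic comparison, 1000
random-ordering replicates (N = 50, k = 6) for aggregation calibration,
and exhaustive Wilcoxon enumeration up to combined sample size 10. These
sizes give Monte-Carlo standard errors small enough for 3-SE bounds to be
meaningful while keeping a full run in tens of seconds on one CPU.

## Known limitations

- Signed/weighted regulons (full three-tailed aREA) are not implemented.
- Only one-vs-rest contrasts; no pairwise cluster testing.
- JASMINE's final score is cohort-dependent by construction.
- The paper-literal aggregation dialect is degenerate for unanimous top
  ranks (see above) and is not the default.
- No HDF5 matrix input, no network access, no species/ID mapping.
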