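# Methods

This note documents the statistical model behind each stage of the
pipeline, the parameters that matter, the design choices made where the
design was genuinely open, and the known limitations — in particular what
the synthetic-data tests do and do not establish about real c-Fos data.

## Study design being modelled

Two independent cohorts of 8 animals perform a temporal-ordering task for
object locations under low (LI) or high (HI) spatial interference.  Per
animal, two measurements exist: exploration times of the older- and
recent-location objects (tOO, tRO, seconds), and a mean c-Fos
positive-cell count in each of 7 regions (PRH35, PRH36, DLENT, DG, CA3,
CA2, CA1), averaged over three tissue sections — hence non-integer.

## Behavior

The discrimination index `D2 = (tOO − tRO)/(tOO + tRO)` lies in [−1, 1],
is antisymmetric in its arguments and invariant to rescaling both times;
positive values indicate preference for the older location, i.e.
spatiotemporal memory.  `D2` is undefined when both times are zero; such
subjects raise an error and are flagged rather than silently dropped.

Per condition, D2 is tested against 0 with a one-sample t-test
(t = mean/(sd/√n), df = n−1); conditions are compared with Welch's
two-sample t (no equal-variance assumption; df fractional).  Shapiro–Wilk
W and p are always computed and reported, but the t-test family is not
switched automatically — a Wilcoxon signed-rank alternative sits behind
`use_wilcoxon_behavior` for non-normal samples.  Effect sizes are
standard Cohen's d (one-sample: mean/sd; two-sample: mean difference over
pooled sd).

## Expression normalization and comparison

Counts are normalized per region to the pooled mean over all 16 animals:
`100 · x / pooled_mean(region)` (equal group sizes make this identical to
normalizing to the mean of the two group means).  The grand mean per
region is exactly 100 by construction.  All downstream statistics are
rank-based, so normalization changes no U statistic, no ρ, and no edge
set — it exists to put group differences on an interpretable percentage
scale.  This rank invariance is asserted by tests.

Group comparisons per region use the Mann–Whitney U test.  For groups of
≤ 8 per side the two-sided p is computed by *full enumeration* of all
C(n_A+n_B, n_A) label assignments over the observed (possibly tied,
mid-ranked) values, with two-sidedness measured as |U − n_A n_B/2|; the
enumeration null is symmetric about that midpoint, so this equals the
usual two-tailed exact p.  Larger groups fall back to scipy's
tie-corrected normal approximation.  Raw p-values are reported by
default; Benjamini–Hochberg adjustment is available behind `adjust="bh"`
but off by default, matching common practice in this analysis family of
reporting uncorrected per-region tests.

## Exact Spearman machinery

All inter-regional and brain–behavior correlations are Spearman's ρ
(Pearson on mid-ranks).  At n ≤ 9 the two-sided p is exact:
P(|ρ_perm| ≥ |ρ_obs|) over all n! orderings.  For tie-free data this
null depends only on n and is cached once per n; with ties (which
resampling with replacement always creates) the null is recomputed for
the specific tie pattern by vectorised gathering of the permuted rank
vectors.  The smallest attainable p is 2/n! and never 0.  At n = 8 the
achievable test size closest to α = 0.05 is 0.0458, which is what the
edge-detection calibration (below) measures.  For n > 9 the standard
t-approximation is used.

## Network construction

Nodes are the 7 regions; an undirected edge joins regions i, j when the
two-sided Spearman p across animals is < α (default 0.05).  Edges carry
the signed ρ; positive and negative edges are counted separately because
the headline quantity of such studies is the number of significant
positive coactivations.  No multiple-comparison correction is applied
across the 21 pairs by default (a BH variant exists behind a flag).
Constant count columns make a region's correlations undefined; the region
stays in the graph as an isolated node but contributes no edges.  Edge
sets are monotone in α, which tests assert.

## Graph metrics

* **degree** — number of incident significant edges.
* **strength** — Σ|ρ| over incident edges (absolute value because
  negative edges are included in the graph but centrality assumes
  positive weights).
* **betweenness** — unnormalized, on weighted shortest paths with edge
  length 1/|ρ| (stronger coactivation = shorter functional distance),
  fractional credit for tied shortest paths.
* **transitivity** — 3·triangles/connected-triples on the *binarized*
  graph (the verbal definition — two nodes sharing a neighbour being
  directly connected — is binary).  Graphs with no connected triples
  report 0 rather than NaN so resampled distributions stay comparable; an
  Onnela-style weighted variant is available behind
  `transitivity_variant="onnela"`.
* **global efficiency** — mean over ordered node pairs of 1/d(i,j) with
  weighted shortest-path distances, 1/∞ = 0.

All five agree with exhaustive brute-force enumeration (all simple paths;
all triads) on 500 random ≤ 6-node graphs, exactly for integers and to
1e−10 for floats.

**Hub rule.**  "Hub" has no standard quantitative definition in this
literature; the operationalization here is: a node ranking in the top k
(default 2, mid-rank ties) on at least two of the three centralities.
Ties that push a rank past k yield no hub call, so fully symmetric graphs
have no hubs.  This rule behaves sensibly (star centre is the unique hub)
but interacts subtly with dense graphs: when every node has the same
degree — e.g. when all 21 pairs are significant at large n — degree
carries no ranking signal and a node must win on both strength and
betweenness to be called.  This is why the planted LI bridge node DLENT,
whose betweenness rank is reliably 2 but whose strength sits just below
the hippocampal nodes, is called a hub in only ~50–65% of large-n
simulations, while DG (bridge-incident *and* strongest node) is called in
every run.  The limitation is a property of the rule, not of the
estimation: with near-threshold weak edges the graph hovers between
"complete" (degree uninformative) and "sparse" (degree informative).

## Bootstrap

Global-metric uncertainty uses a subject-level bootstrap: B = 100
replicates resample the 8 animals with replacement and recompute the
entire chain (exact Spearman matrix with ties, threshold, metrics).
Replicates where a region's resampled column is constant drop that
region's correlations for the replicate (logged).  This is the only
reading of "resampling the correlation matrix" that yields a sampling
distribution of network metrics; the alternative (resampling matrix
entries) destroys the subject structure the correlations come from.

The between-condition comparison applies a two-sided Wilcoxon rank-sum to
the two bootstrap distributions (B values each) and reports the condition
with the larger median.  Treating resamples as independent observations
is anticonservative — the effective sample size is 8 animals, not 100
resamples — and this caveat is surfaced in the run log; the procedure is
implemented as published practice for this family of analyses.

## Shuffled null

The chance model permutes the off-diagonal upper-triangle (ρ, p) pairs of
the observed correlation matrix uniformly at random, mirrors the result,
and keeps the unit diagonal fixed.  Every replicate preserves symmetry,
the diagonal, and the off-diagonal value multiset — and, because p
travels with ρ, the thresholded edge count.  A joint row/column
permutation was rejected: it produces a graph isomorphic to the observed
one, with identical global metrics (a vacuous null).  The implemented
null therefore asks: *given this many significant correlations of these
strengths, is the observed metric extreme for where they sit?*

Empirical p-values use the add-one estimator
`(1 + #{null ≥ obs})/(1 + N)` (direction `greater`; `less` and
`two_sided` available), so p ∈ (0, 1] always.

**Calibration caveat.**  Because the edge count is preserved, networks
with 0 or 1 edges have *all* null values identical to the observed value
(p = 1), and sparse networks have only a handful of distinct placement
classes.  Under exchangeable noise the test is therefore valid but
strongly conservative: across 500 independent-region simulations the
rejection rate at α = 0.05 is ≈ 1% for transitivity and ≈ 0% for
efficiency, not the nominal 5%.  A test asserts the conservative
direction (rate ≤ nominal); users should read non-significant chance
tests on sparse networks as uninformative rather than null-confirming.

## Louvain modules and resolution selection

Communities are detected on the positive-edge subgraph with |ρ| weights
(Newman modularity is undefined for signed graphs; negative edges are
excluded).  Isolated nodes become singleton communities; a network with
no positive edges yields the all-singleton partition with modularity 0
and a warning.  The implementation is networkx's seeded Louvain;
community ids are renumbered 1..k by first appearance in the region
ordering so partitions are deterministic given a seed.  On planted
7-node graphs the achieved modularity is checked against the exhaustive
maximum over all 877 set partitions: it never exceeds it and reaches it
in ≥ 95% of seeded runs.

The resolution γ is selected by stability: for each γ on a grid (default
0.5–1.5, step 0.1), Louvain runs `reps` = 100 times per condition with
distinct derived seeds; the per-condition stability is the frequency of
the modal community count, the score is the sum over the two conditions,
and ties break toward the smallest γ.  "Most-repeated community count"
is the chosen operationalization of reproducibility; a partition-level
alternative (mean pairwise adjusted Rand index) is available via
`criterion="rand"`.

## Synthetic generator

The generator emulates the two regimes the analysis must distinguish,
not the biology of c-Fos expression:

* **Latent correlation.**  Per condition, region pairs get `rho_within`
  (same block), `rho_bridge` (listed bridge pairs), or `rho_between`
  (otherwise).  The LI-like preset uses blocks {DG, CA3, CA2, CA1} and
  {PRH35, PRH36, DLENT}, within 0.85, between 0.05, bridge
  (DLENT, DG) = 0.8; the HI-like preset is one block at 0.8.  The raw
  LI construction is not positive semi-definite; it is repaired by
  eigenvalue clipping and diagonal rescaling (tolerance 1e−8), and the
  maximum elementwise change is reported (0.26 for the LI preset — the
  bridge relaxes to ≈ 0.54 and DG's within-block entries to ≈ 0.74).
  The repaired matrix is the actual data-generating structure.
* **Counts.**  A Gaussian copula maps the latent normal draws through a
  lognormal quantile (mean 80 cells, log-sd 0.4 — a typical
  per-section count scale with realistic right skew), rounded to 0.1 and
  floored at 0.1.  Because the pipeline is rank-based, any monotone
  marginal would give the same networks; the latent Pearson ρ appears
  downstream as Spearman ρ_s = (6/π)·asin(ρ/2) (e.g. 0.85 → 0.838).
* **Behavior.**  Per subject, D2 ~ Normal(mean, sd) resampled into
  (−0.999, 0.999), combined with a lognormal total exploration time
  (mean 30 s, log-sd 0.3) to give strictly positive tOO, tRO.  Preset
  means/sds (LI 0.35 ± 0.2, HI 0.35 ± 0.105) were chosen so the
  one-sample t against chance lands near the magnitudes such studies
  report (t(7) ≈ 4–9).

What passing tests show: the pipeline detects planted block structure,
bridges, and integration differences at the stated power, with exact
small-sample inference.  What they do not show: anything about real
c-Fos data — real counts have section-level variance components,
inter-region mean differences, and condition effects on expression level,
none of which are modelled (and the last of which the reference analysis
explicitly found absent).

## Problem sizes and numerical choices

Simulation-based tests use n = 2000 subjects for structure-recovery
checks (sampling error of ρ ≈ 0.02, well below the planted contrasts)
and the study's n = 8 for power demonstrations; calibration checks use
2000 (edge rate) and 500 (chance test) replicates, chosen to give
Monte-Carlo standard errors well inside the asserted bands.  Exact-test
comparisons stop at n = 7 (full n! enumeration) plus a 50,000-permutation
Monte-Carlo spot check at n = 8.  Ties use mid-ranks everywhere;
permutation comparisons use a 1e−9 slack so boundary cases count as ties
rather than flipping on float noise.  All resampling seeds derive from a
single configured seed via numpy SeedSequence spawning, making every
report a pure function of (inputs, config).

## Known limitations

* n = 8 networks are intrinsically unstable: with all pairs equally
  correlated (HI-like), sample correlations move together and whole-
  network failure draws (1–3 detected edges) occur in >10% of cohorts.
  Between-condition comparisons inherit that instability regardless of
  the comparison test.
* Binary transitivity of a sparse two-block network is often 1.0 (its
  detected edges form small cliques), so "more integrated ⇒ higher
  clustering" does *not* hold for the planted regimes at small n, even
  though it may hold in a given real dataset.
* The shuffled null is conservative (see above); the Wilcoxon-on-
  bootstrap comparison is anticonservative.  The two do not cancel; they
  answer different questions.
* Hub calls at the default k = 2 are sensitive to degree ties in dense
  graphs (see the hub-rule discussion).
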