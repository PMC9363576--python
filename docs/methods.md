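# Methods

This note documents the statistical methods implemented in `imsubtype`,
the default parameters and why they are set that way, the scope of the
synthetic-cohort generator, and the numerical conventions that make the
pipeline deterministic.

## 1. Input model and preprocessing (`imsubtype.io`)

Expression is a genes × samples matrix on one of two declared scales,
`TPM` or `LOG2_TPM1` (= log2(TPM + 1)); every transform checks the
declared scale so a matrix cannot be log-transformed twice or scored on
the wrong scale. `filter_expressed_genes` keeps genes with TPM > 0 in
strictly more than `min_prop = 0.3` of samples (applied on the TPM
scale; idempotent). Duplicate gene rows read from disk are collapsed by
the per-sample maximum with a warning; duplicate sample columns are an
error. Survival tables carry `time_days` (≥ 0) and `event` ∈ {0, 1};
mutation tables carry (sample, gene, variant class) records with a
standard 17-class variant vocabulary, the first 9 of which count as
nonsilent.

## 2. Single-sample enrichment scoring (`imsubtype.scoring`)

For one sample, genes are ranked by expression (highest = N, average
ranks for ties) and walked in decreasing order. With member set G and
weight exponent α:

- P_in(i)  = Σ_{g ∈ G, pos ≤ i} rank(g)^α / Σ_{g ∈ G} rank(g)^α
- P_out(i) = |{g ∉ G, pos ≤ i}| / (N − |G|)
- ES       = Σ_i (P_in(i) − P_out(i))

Defaults: α = 0.25; `normalize=True` divides all scores by the global
range max(ES) − min(ES) across the whole matrix, the standard
normalization that makes signatures comparable. Scoring requires the
`LOG2_TPM1` scale. A set with fewer than 2 matching genes is excluded
and recorded in `missing_`; a set covering every gene in the matrix is
an error (P_out undefined). Worked check kept in the tests: 4 genes
with expression 4 > 3 > 2 > 1, G = {g1, g3}, α = 1 gives ES = 4/3.

Convenience scores: cytolytic activity is the arithmetic mean of the
GZMA and PRF1 log-expressions (a geometric-mean-of-TPM option adds a
0.01 TPM offset before the log); `estimate_scores` returns
stromal + immune signature scores and their sum.

## 3. Prognostic screen (`imsubtype.screen`)

Univariate Cox proportional hazards per signature, written in-house:
Newton–Raphson from β = 0 on the Breslow partial likelihood (tied event
times share the full risk set; risk sets via suffix cumulative sums),
step-halving on likelihood decrease, convergence tolerance 1e-9, Wald
p-value. The covariate is standardized to unit variance by default so
step sizes are well-scaled; the p-value is invariant to this. A
monotone (fully concordant) covariate has an infinite MLE; the solver
reports this as a convergence error rather than returning a spurious
estimate. `lifelines` is used as an independent cross-check in the test
suite, and directly for Kaplan–Meier curves, the multivariate log-rank
test, and restricted mean survival time.

Screen defaults: samples with follow-up < 30 days are excluded;
selection threshold p < 0.05 (unadjusted, matching the original
two-cohort screen design; Benjamini–Hochberg available via
`adjust="BH"`). `overlap_filter` requires ≥ 2 cohort reports and keeps
signatures selected in at least `min_cohorts = 2` of them, sorted by
(−support count, name) for determinism.

## 4. Consensus subtyping (`imsubtype.consensus`)

PAM (k-medoids) is hand-written and deterministic: greedy BUILD
initialization followed by full SWAP descent, ties broken toward the
lowest index; no randomness is consumed.

Consensus clustering: `n_resamples = 500` subsamples of
⌈0.8·n⌉ samples drawn without replacement (80 % subsampling is the
established consensus-clustering resampling scheme), PAM on Euclidean
distances for each k ∈ [2, 10]. The consensus matrix M_k is the
co-cluster count divided by the co-sample count per pair; pairs never
co-sampled are set to 0 and flagged. The area under the empirical
consensus CDF is the exact step integral Σ (x_{i+1} − x_i)·F(x_i) — not
the trapezoid rule — because the step integral is the formula of the
canonical consensus-clustering implementation and is exact for a step
function (a perfect 0/1 consensus matrix then gives area = fraction of
zero pairs). Δ(2) = A(2) and Δ(k) = (A(k) − A(k−1))/A(k−1);
`suggest_k` is the argmax of Δ over k ≥ 3 (Δ(2) is not comparable).

Final labels: average-linkage hierarchical clustering of 1 − M_k cut
into k groups. `order_by_prognosis` renames groups IS1…ISK by
increasing restricted mean survival time (horizon = largest observed
time), so **IS1 is always the worst-prognosis subtype**; RMST ties
produce a warning and keep the original order.

## 5. Cross-cohort validation (`imsubtype.validate`)

Subtype centroids are per-signature mean score vectors.
`NearestCentroidProjector` assigns each validation sample to the
centroid with the highest Pearson correlation (requires ≥ 80 % feature
overlap; samples that are constant across features fall back to
Euclidean distance and are tracked in `euclidean_fallback_`). The
in-group proportion (IGP) of a subtype is the fraction of its members
whose nearest neighbor (1 − Pearson, or Euclidean) carries the same
label; singletons score 0 and are flagged. `centroid_correlation`
greedily matches discovery to validation centroids by descending
correlation.

## 6. Characterization (`imsubtype.characterize`)

Kaplan–Meier curves per subtype with the K-group log-rank test
(samples with < 30 days of follow-up excluded, as in the screen). TMB
is the nonsilent record count per sample (optionally per megabase);
samples absent from the mutation table get 0 with a warning. The
mutation-frequency screen tests each gene mutated in strictly more than
`min_count = 3` samples of at least one subtype with a chi-square on
the 2 × K mutated/unmutated table (no continuity correction).
Continuous features use Kruskal–Wallis across subtypes plus pairwise
two-sided Wilcoxon rank-sum tests; zero-variance degenerate inputs
yield p = 1 rather than NaN. Categorical factors use Fisher's exact
test for 2 × 2 tables and chi-square otherwise, with a seeded
Monte-Carlo permutation option for sparse larger tables.

## 7. Co-expression modules (`imsubtype.coexpr`)

Genes are pre-filtered by median absolute deviation (`top_prop = 0.5`;
constant genes are always dropped when top_prop < 1). Adjacency is
|Pearson r|^β with the soft threshold β = 10 (a `signed` option keeps
((1 + r)/2)^β). Topological overlap:

TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

with k = row sums of a minus 1 (worked check: the 3-gene example gives
TOM_12 = 0.88/1.2 = 0.7333…). Modules come from average-linkage
clustering of 1 − TOM with a **simplified dynamic tree cut**:

- cut height = min(quantile(merge heights, 0.99 − 0.01·deep_split),
  0.99 · max height), `deep_split = 4`. The 0.99·max cap mirrors the
  reference dynamic-tree default (99 % of the dendrogram height range)
  and is required: a pure-noise dendrogram has all merge heights in a
  narrow band near 1, and the raw quantile would slice inside that band
  and produce spurious large "modules".
- branches with ≥ `min_size = 60` genes become seed modules; remaining
  genes are rescued into the module where their kME (correlation with
  the module eigengene) is highest, if kME ≥ 0.5 — a conventional
  membership threshold midway between "unassigned" and the hub cutoff —
  otherwise they stay grey (unassigned).
- the eigengene is the first principal component of the standardized
  member expression, with its sign fixed so the mean kME is positive;
  modules whose eigengenes satisfy 1 − cor < `merge_height = 0.25` are
  merged iteratively.
- modules are named with the conventional color sequence by size.

Hub genes are module members with kME strictly > 0.85 **and**
univariate Cox p < 0.05 against the supplied survival. Module–trait
relationships are Pearson correlations between eigengenes and traits.

## 8. Synthetic cohorts (`imsubtype.simulate`)

The generator's defaults are the study conditions: 2000 genes, 150
samples, K = 3 subtypes at prevalences (0.4, 0.2, 0.4), 6 disjoint
25-gene signatures (signature s is up-regulated in subtype s mod K
with effect size 1.0 on the log2 scale), residual noise SD 1.0,
exponential disease-free survival with per-subtype hazard ratios
(2.5, 1.35, 1) — subtype 0 is the planted worst, the middle subtype
intermediate — at a baseline rate of 1/2000 per day, and an
independent exponential censoring time whose rate is solved
numerically (Brent's method) to give an expected 10 % censoring. The
survival defaults are deliberately well-powered: the log-rank
noncentrality is roughly the event count times the
prevalence-weighted variance of the group log-hazards, and with 150
samples and the worst-vs-best hazard ratio fixed at 2.5 the
three-group test at α = 0.01 reaches ≈ 96 % power only under light
censoring with the extreme subtypes weighted; the chosen defaults make
prognosis-ordering recovery (measured ≈ 99 % of seeds) and log-rank
separation (≈ 96 %) reliable study conditions rather than coin flips,
while keeping the middle subtype prognostically intermediate so both
the worst-linked and best-linked signatures remain detectable by the
Cox screen. Mutations are Poisson counts with per-subtype mean TMB
(5, 10, 20) split over three nonsilent classes plus silent records at
0.3 × the nonsilent rate. Expression is emitted as TPM = 2^(log2) − 1
so the pipeline's own filtering/log steps are exercised. Structure
(gene means, signature membership) is derived from `cfg.seed`; sample
realizations from a separate `sampling_seed`, so a discovery/validation
pair shares structure but not samples. `simulate_block_expression`
separately plants correlated gene blocks (shared latent factor,
within-block correlation 0.8) for module-recovery checks.

The generator emulates: subtype-separated signature scores, proportional
hazards survival with planted ordering, censoring, TMB differences, and
block co-expression. It does **not** emulate: realistic count noise
(negative binomial), library-size/batch effects, correlated censoring,
copy number, immune-cell deconvolution ground truth, or inter-signature
gene overlap. The bundled GMT collections are synthetic surrogate
lists, not published signatures.

## 9. Determinism and seeds

All randomness flows through `numpy.random.default_rng`. The pipeline
derives one independent stream per stage with
`np.random.SeedSequence(entropy=seed, spawn_key=(stage,))`, reduced
mod 2^31 so every materialized seed fits a signed 32-bit int. PAM and
hierarchical clustering are fully deterministic; all tie-breaks go to
the lowest index (PAM swaps, nearest-neighbor/centroid assignment).
`imsubtype run` writes a manifest with the resolved configuration,
stage seeds, and SHA-256 hashes of every output file; identical seeds
reproduce identical bytes. The test suite asserts bitwise determinism
on a reduced problem size (fewer genes/samples/resamples) chosen by the
package so the whole suite stays within a practical runtime budget;
`scripts/acceptance.py` runs the full default-size study.

## 10. Limitations

- The Cox screen is univariate and unadjusted by default; it screens,
  it does not model confounding.
- The simplified dynamic tree cut is a static-height approximation of
  adaptive branch cutting; fine nested module structure that the
  adaptive algorithm would resolve can be merged or missed.
- ssGSEA normalization uses the global score range of the supplied
  matrix, so normalized scores depend on the signature collection
  scored together.
- IGP is reported without its permutation null; values are descriptive
  reproducibility measures, not p-values.
- The PAM SWAP search is a local descent from the BUILD start; like all
  k-medoids implementations it can return a local optimum, but it is
  deterministic.
- Synthetic surrogate gene sets make the bundled pipeline self-contained
  but carry no biological meaning.
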