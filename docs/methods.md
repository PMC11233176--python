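# Methods

## Model and assumptions

A bulk expression profile is modeled as a bag of gene tokens drawn from a
mixture of K latent topics. Sample-topic weights θ_m and topic-gene
distributions φ_k carry symmetric Dirichlet priors α and η; tokens are
generated by `z ~ Multi(θ_m)`, `g ~ Multi(φ_z)`. Inference is collapsed
Gibbs sampling on the token assignments with θ, φ integrated out; the
per-token conditional is the usual product of smoothed count ratios, and
convergence is monitored via the collapsed joint log-likelihood
(log-gamma form of the Dirichlet-multinomial marginal).

The identification assumption is that each guided topic's marker genes are
expressed predominantly by its cell type, so seeding every marker token
into its topic — and refreshing marker assignments only with a small
probability thereafter — pins topic identities without using any reference
expression levels. The estimated θ is read as cell-type proportions of the
token pool, which tracks mixing proportions when library composition is
roughly proportional to cell content; no mRNA-content-per-cell correction
is applied.

## Preprocessing

* Input must be linear-scale (non-log), non-negative expression with genes
  as rows. Gene names are matched after whitespace trimming and
  case-folding; duplicate rows are collapsed by sum with a warning.
* Outlier filter: the per-gene statistic is `log(mean expression + 1)`
  (pseudocount 1); genes more than `sigma` (default 2) population standard
  deviations **above** the mean of that statistic are dropped. The filter
  is upper-tail only — it targets consistently over-expressed
  mitochondrial/ribosomal-like genes; two-sided trimming would throw away
  informative low-expression markers. Marker genes are exempt.
* Analysis genes = markers present in the matrix plus the `topn` highest
  coefficient-of-variation (sd/mean, linear scale) non-marker genes.
  Suggested `topn`: 100 for blood, 1000 for heterogeneous tissue. Genes
  with zero mean get CV 0; ties break lexicographically so the selection
  is reproducible.
* Tokens are obtained by rounding expression to the nearest integer
  (half-up). No per-sample depth rescaling is applied by default; the
  `scale_depth` option rescales each column to a common token depth first.
  Rounding changes the total token mass of an L×M corpus by at most
  0.5·L·M.

## Sampler

* Defaults α = η = 0.01 (symmetric). Sparse priors reflect the expectation
  that a sample contains few cell types and a topic loads few genes;
  estimates are insensitive to the exact value in the (0, 1] range used
  here, and both are exposed as configuration.
* `refresh_prob` = 0.01: marker tokens are nearly pinned, but a small
  refresh lets the data adjust a marker's contribution when it disagrees
  with the guide. 0 pins markers exactly.
* Chain length: 200 sweeps, burn-in 100, log-likelihood recorded after
  sweep 1 and every 10th sweep. These lengths give stable estimates at the
  corpus sizes this package targets (10⁴–10⁶ tokens); convergence is
  monitored, not auto-stopped.
* θ/φ estimator: smoothed-count posterior means of the final state
  (`avg_window` = 1). Setting `avg_window` > 1 averages the last recorded
  post-burn-in states instead; with a near-pinned guide there is no
  label-switching within a chain, so averaging is safe but was not found
  necessary.
* Token visitation order is fixed (sample-major, gene-major), and all
  per-sweep randomness is pre-drawn from a seeded NumPy generator, so a
  trajectory is a pure function of the seed. The numba-JIT kernel and the
  pure-NumPy fallback consume the same uniform streams and produce
  bit-identical trajectories.
* A gene appearing in several marker sets splits its tokens uniformly
  among those topics at initialization and refreshes like any marker.
  High-CV non-marker genes are sampled freely over all K topics.

## Ensemble and median selection

Gibbs estimates depend on the seed, so En = 10 independent chains (seeds
0–9 by default) are run and θ is aggregated by entrywise median followed
by per-row renormalization — median first, then renormalize, which is what
guarantees the reported proportions sum to 1. Guided topics need no
cross-run alignment (the guide pins their identity). Additional topics are
*not* identifiable across runs and are therefore never medianned; their
per-seed φ rows are kept as a stack for downstream clustering. φ of guided
topics is aggregated by entrywise median for reporting only.

## Choosing the number of additional topics

For K_u = 1, 2, …: fit the model (entrywise-median φ over a fixed scan
seed list, default 3 seeds), restrict to non-marker genes, pool each added
topic's top floor(L′/K) contribution genes, and compute the K_u × K
Pearson matrix between added-topic and all-topic contribution profiles
over the pooled genes. "Significantly positive" is operationalized as a
one-sided Pearson test p < 0.05 (configurable); the self-pair is excluded;
comparisons against guided topics count. The scan stops at the first
redundant fit and returns the previous K_u (0 if K_u = 1 is already
redundant); hitting `max_Ku` without redundancy returns `max_Ku` with a
warning. Each candidate refits from scratch so the scan is a deterministic
function of the seed list.

**Limitation.** On small pooled-gene sets (~10–20 genes) the correlation
decision is noisy: all topics' raw contributions scale with gene
abundance, excess topics tend to *split* a duplicated gene block (yielding
negative, undetected correlations) rather than duplicate it, and residual
Poisson noise peeled into guided topics can fire the test spuriously. The
packaged hidden-factor generator (`make_hidden_factor_bulk`) constructs a
regime where the decision is stable — a single rank-1 hidden factor whose
block dominates the CV selection, with activity independent of the guided
mixture — and the scan's behaviour there (keep 1, reject 2) is verified
across disjoint seed lists. On real tissue, treat the selected K_u as a
starting point and inspect the redundancy reports.

## Topic interpretation

* The (K_u · En) × L stack of additional-topic contributions is clustered
  by k-means (K_u clusters) after L2 row normalization, so clusters
  reflect contribution shape rather than chain-specific scale. Cluster
  labels are arbitrary; only the partition and centroids are used.
* Each centroid's top floor(L/K_u) genes are tested per annotation set by
  the one-sided (over-representation) Fisher's exact test — the
  hypergeometric upper tail of the 2×2 table — with Benjamini–Hochberg
  adjustment across sets. The background universe is the **analysis gene
  list** (the genes the model saw), not the genome: enrichment against the
  genome would mostly re-discover the CV filter.
* The single-sample enrichment score is a weighted Kolmogorov–Smirnov
  running sum down the contribution-ranked gene list: member genes add
  their |contribution| (exponent 1) normalized over the set, non-members
  subtract 1/(L − |set|); the score is the maximum deviation from zero
  with sign. A rank-weight variant (weights L − rank) makes the score
  invariant to monotone transforms of the contributions. A set covering
  the whole universe scores 0 by convention.

## Synthetic data

`SyntheticDesign` defaults describe a clearly separable mixture:
K_true = 5 cell types, L = 300 genes, 10 private markers per type at
20-fold elevation over baseline 10, log-normal gene-level variation
(σ = 0.5) on background genes, depth 20 000 tokens per sample, Poisson
counting noise (negative binomial optional), and Dirichlet(1) true
proportions; M = 20 samples in the standard harness. Contaminant types
(own markers, excluded from the guide) exercise additional-topic
absorption. These sizes keep a full ensemble run in seconds on one CPU
while leaving the recovery problem non-trivial.

What the generator does **not** emulate: cell-to-cell heterogeneity within
a type, batch effects beyond gene-level noise, mRNA content differences
between types, zero-inflation, and correlated marker programs shared
between related cell types. Passing recovery tests on this generator shows
the inference machinery is correct and well-conditioned on separable
mixtures; it does not certify performance on real tissue, where marker
quality dominates.

## Numerical and degenerate-input choices

* Count tables are int64 and updated incrementally; a consistency
  validator (tables vs token assignments) is used as a bug trap in tests.
* Zero-count topics have prior-uniform φ rows by construction of the
  smoothed estimator.
* Constant vectors make Pearson r undefined: redundancy pairs are logged
  and treated as non-redundant; recovery scores report NaN.
* Deterministic tie-breaks throughout: lexicographic gene name in CV
  selection, top-gene pooling and centroid top lists.
* The median of an even number of runs is the midpoint of the two central
  values.

## Problem sizes used by the test suite and acceptance script

Unit tests use corpora of 10–10⁴ tokens with exact oracles (sequential
Polya-urn factorization of the joint, brute-force hypergeometric tails,
enumerated stationary distributions). End-to-end checks use the default
design (5 types × 20 samples, depth 20 000, 10-seed ensembles); the
variance-reduction comparison uses 50 single chains vs 5 ensembles of 10.
The acceptance script regenerates all inputs from its `--seed` and
finishes in a few minutes on one CPU.
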