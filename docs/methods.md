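# Methods

This note documents the model, the numerical choices, and the design
decisions behind `dice-net`, in the spirit of a statistical software
methods appendix. It states no empirical result beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## The model

DiCE (differential centrality-ensemble) assumes that condition-relevant
genes manifest in two partly disjoint ways: as **differentially expressed
genes** (mean shifts between conditions) and as **rewired genes**, whose
co-expression with their interaction partners changes even when their own
level barely moves. The pipeline scores the second kind by embedding both
conditions in the *same* PPI topology and asking how much each gene's
position-dependent importance changes.

Two centrality measures are combined because they capture complementary
aspects of importance: weighted betweenness (how often a gene lies on
shortest paths — a bottleneck/bridge role, computed on the
`1 − |c.c.|` distances) and eigenvector centrality (recursive influence —
being connected to strongly connected genes, computed on the `|c.c.|`
affinities). Their absolute cross-condition differences are aggregated by
a rank product: each |Δ| vector is ranked in descending order, ranks are
mapped to [0, 1] by `(N − r)/(N − 1)`, and the score is the product. Rank
products are scale-free (invariant to any positive rescaling of either
Δ vector) and favor genes consistently high in both measures.

## Interpretation choices the literature leaves open

* **Eigenvector weights.** Shortest-path distances (`1 − |c.c.|`) cannot
  be fed to the eigenvector recursion, which needs "larger = stronger"
  weights; this package uses the affinity `|c.c.|`. This is the single
  most consequential interpretation in the package and is switchable
  (`eigen_weight: affinity | unweighted`).
* **Betweenness normalization.** Values are divided by `(n−1)(n−2)/2`
  (undirected, endpoints excluded) so the two equally-sized condition
  networks are comparable and values live in [0, 1].
* **Discretization for information gain** is not dictated by the IG
  formulas, which treat expression levels as discrete. Default:
  equal-frequency bins, `bins = min(10, ⌊N/3⌋)` with a floor of 2, which
  makes IG invariant under monotone transforms and robust to outliers in
  z-scored data. Equal-width and distinct-value modes are available; the
  distinct-value reading degenerates for continuous data (every value its
  own level ⇒ IG = D for all genes) and is therefore not the default.
* **Mean-exclusion conjunction.** "Excluded when centrality is below the
  average in both conditions" is ambiguous across the two measures. The
  default `all_below` excludes a gene only when it is below the mean for
  *every* measure in *every* condition (most conservative); the stricter
  `either_measure_below` mode excludes as soon as one measure is below its
  mean in both conditions. Means are taken over all network genes.
* **Normalization endpoints.** `(N − r)/(N − 1)` maps the bottom rank to
  exactly 0, so finishing last in either measure zeroes the product. This
  follows "1 is the highest importance, 0 the lowest" literally; it makes
  the bottom of the ranking degenerate (many exact zeros), which is
  harmless for the top-of-list use case but worth knowing.
* **Exclusion timing.** All network genes are ranked first and exclusions
  are flagged afterwards, so the output table supports both the
  "rank-then-filter" and "filter-then-rank" readings.
* **ORA background.** Default universe = the Phase-III network genes;
  `universe: expressed` uses all matrix genes. Annotation servers differ
  here and results are sensitive to it. The plain hypergeometric upper
  tail is the default statistic; the EASE-style conservative variant
  (overlap k − 1) is a flag.

## Numerical choices

* Welch's t (unequal variances) is the internal DE fallback, paired t on
  per-pair differences for paired designs; an external limma/edgeR table
  is the recommended path and bypasses it. Degenerate genes are handled
  deterministically: zero variance in both groups ⇒ p = 1; constant
  non-zero paired difference ⇒ p = 0 (the diverging-t limit), logged.
* Threshold inequalities are strict (p/q strictly below, |log2FC| strictly
  above), so boundary genes are excluded; the IG filter likewise keeps
  only genes strictly above the pool mean, with an all-tied fallback that
  retains everything rather than emptying the pipeline.
* Z-scoring uses the sample standard deviation (ddof = 1); constant rows
  map to zeros (warning) so correlations stay defined. Undefined edge
  correlations (zero-variance endpoint within a condition) are set to 0
  (distance 1), counted and logged.
* Zero distances (|c.c.| = 1) are kept as true zeros — valid for Dijkstra;
  no epsilon flooring.
* Eigenvector centrality: power iteration on `A + I` (the +1 diagonal
  shift leaves eigenvectors unchanged and breaks the ±λ tie on bipartite
  graphs), tolerance 1e-10 on the L∞ change of the normalized vector.
  The per-call default of 1000 iterations is raised to 5000 in the
  pipeline configuration, since disconnected IG-induced subgraphs can
  have slowly separating component spectra; non-convergence raises an
  error reporting the residual. Minor components converge to (near-)zero
  entries, giving one consistent global ranking; per-component analysis
  can be had by running components separately.
* Ties in the final ordering are broken by larger Δbetweenness, then
  lexicographic gene symbol, making output files reproducible
  byte-for-byte. All writers use shortest-round-trip float formatting, so
  any phase can be replayed exactly from its written TSV (readers parse
  with `float_precision="round_trip"`).

## The synthetic-data generator

The generator emulates the data regime the method targets, not any
particular cohort. Per study: a preferential-attachment (scale-free)
scaffold (default 300 genes, attachment 5 ⇒ ~1475 edges with pronounced
hubs); per-edge target correlations drawn uniformly from ±(0.4, 0.8);
a Gaussian copula — per condition the target matrix (non-edges 0) is
projected to the nearest positive-definite correlation matrix by iterated
eigenvalue clipping (at 1e-6) plus unit-diagonal rescaling, Cholesky
factored, and sampled as multivariate normal with marginal sd 0.4 on the
log2 scale around a base mean of 8.

Two feasibility details matter:

* **Degree-aware damping.** A hub cannot correlate at ~0.6 with dozens of
  mutually uncorrelated neighbors — such a target matrix is far from
  positive definite and projection would erase the planted structure. Each
  edge target is therefore scaled by `min(1, 0.9/ν_i, 0.9/ν_j)`, where
  `ν_i` is the root-sum-square of gene i's edge targets. After damping the
  projection moves no correlation by more than 0.1 (tracked per run and
  enforced; measured values are ≤ ~0.06).
* **Rewiring = correlation attenuation on hubs.** Rewired genes are drawn
  from the top degree decile and their incident-edge target magnitudes are
  reduced by `rewire_drop` (default 0.6, floored at 0.05) in the second
  condition only. Attenuation is exactly the mechanism the method assumes:
  it lengthens shortest paths through the gene (betweenness drops) and
  weakens its affinities (eigenvector drops). Hubs are used because
  rewiring a leaf barely perturbs any path — and because only
  well-connected genes remain connected once the information-gain filter
  thins the network; this matches the method's own premise that its
  targets are high-connectivity genes. Rewired genes also receive a subtle
  mean shift (|log2FC| = 0.3, random sign) so they are realistically
  "present but sub-threshold" for conventional DEA; planted DEGs (default
  20) get |log2FC| = 1.0 and untouched correlations.
* **Confidence model.** When heterogeneous edge confidences are requested,
  they are rank-matched to the summed endpoint degree (with seeded
  jitter): interaction evidence in STRING-like resources concentrates on
  well-studied, well-connected proteins, so stringent confidence filtering
  retains a coherent hub backbone rather than a random sparse subgraph.

What the generator does **not** emulate: count noise (it is Gaussian on
the log scale, not negative-binomial), batch effects, correlated
background fold changes, cellular heterogeneity, and annotation structure.
Passing tests therefore demonstrate the pipeline's mechanics and its
claimed qualitative advantage (recovering rewired genes that DEA misses)
under a controlled generative model — not performance on any real cohort.

## Recommended usage for rewiring-focused screens

Rewired genes are, by construction, marginally weak. The information-gain
filter keeps genes above the *pool mean* IG, so it only retains weak-but-
rewired genes when the pool mean is diluted by null genes. Consequently
the end-to-end demonstrations run Phase I wide open (p < 1.0): the pool is
the whole gene universe and Phases II–V do the filtering. With a
conventional loose screen (p < .05) the pool becomes signal-dominated and
the IG filter removes precisely the subtle genes the network phases were
meant to rescue. On real transcriptome-scale data (tens of thousands of
genes, most of them weakly perturbed) a loose Phase-I screen plays the
same pool-diluting role; on small simulated universes it cannot.

## Problem sizes

Tests and the acceptance script use the generator's default study size —
300 genes, 60 samples per condition, 10 rewired genes, 20 DEGs, 10 seeds
for the recovery experiment, 20 seeds for null calibration — which the
package treats as its standard simulated cohort: large enough for stable
correlation estimates (sampling sd ≈ 0.13 per edge at n = 60) and clear
hub structure, small enough to iterate on quickly.

## Known limitations

* Exactly two conditions end-to-end (the entropy/IG code handles k
  classes, but Phases III–V assume two networks).
* Identifier mapping is out of scope: gene symbols are opaque and
  case-sensitive, and must match between the expression matrix and the
  edge list.
* Correlations are plain Pearson on all samples of a condition (no
  pairing-aware or shrinkage estimators).
* The eigenvector/affinity interpretation and the mean-exclusion
  conjunction are documented choices among defensible readings (above);
  both are configurable.
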