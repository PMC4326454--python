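# Methods

## Problem and model

Differential co-expression is a change, between phenotype groups, in the
*correlation* of two genes' expression rather than in either gene's mean.
A gene can sit at the centre of many such rewired edges — a susceptibility
hub — while showing no univariate effect at all, which is exactly the
signal a per-gene differential-expression test cannot see. `netgain`
identifies such hubs in three stages: infer a gene-gene interaction matrix
from case-control expression data, rank genes by a network centrality over
that matrix, and convert scores to significance calls with an empirical
null.

### Interaction matrices (GAIN)

Both inference routes produce an N×N symmetric matrix A with main effects
on the diagonal and pairwise interaction scores off it.

**dcGAIN.** For each gene pair (i, j), Pearson correlations r¹ᵢⱼ and r⁰ᵢⱼ
are computed separately within cases (group sizes m₁) and controls (m₀),
Fisher-transformed z = atanh(r), and compared:

    Zᵢⱼ = |z(r¹ᵢⱼ) − z(r⁰ᵢⱼ)| / √(1/(m₁−3) + 1/(m₀−3))

This is the classical two-sample z-test for a correlation difference;
off-diagonals are non-negative magnitudes. The diagonal is a Welch
two-sample t-statistic per gene (the unequal-variance form is the safe
default for expression data). Each group needs more than 3 samples or the
denominator is undefined. Correlations are clamped to ±(1 − 1e−7) before
the transform so degenerate (perfectly correlated) simulated pairs stay
finite. A flag switches the transform to atanh(|r|), which discards the
sign of r; the two variants differ only when a pair's correlation changes
sign between groups. A zero-variance gene within a group gets correlation
0 to every other gene, with a logged warning.

**reGAIN.** For each unordered pair, a GLM with a full multiplicative
interaction:

    g(E[D]) = b₀ + bᵢGᵢ + bⱼGⱼ + bᵢⱼGᵢGⱼ (+ covariates)

with logit link for case/control outcomes and identity for quantitative
traits. Gene predictors are z-scored and the product term is built from
the z-scored genes, so coefficients are standardized. The matrix element
is the Wald z-statistic bᵢⱼ/SE(bᵢⱼ) by default — Wald puts the single-gene
diagonal (from `D ~ b₀ + bᵢGᵢ`) and the interaction off-diagonal on a
common scale for the centrality step — with the raw standardized
coefficient available via `stat="beta"`. Off-diagonals are signed.

All pair models are fitted simultaneously by a batched Newton/IRLS solver
(one (pairs × samples × 4) design tensor, batched 4×4 solves). This is an
exact fit, verified against per-pair GLM fits to ~1e−7, and is what makes
permutation nulls over full matrices affordable: one N = 100 matrix takes
a fraction of a second instead of thousands of independent model fits.
Pairs whose unpenalized logistic fit does not converge — complete
separation is routine at 20–40 samples — are refitted with an L2 ridge
(default scale 0.1, intercept unpenalized) and logged; the matrix is
always total. Non-convergence is declared after 30 Newton iterations
(logistic Newton converges quadratically; anything still moving after 30
steps is separated) or when any coefficient exceeds 10³.

### Centrality (CINC)

Gene importance R solves the N-equation linear system

    Rᵢ = Aᵢᵢ/(N·Tr A) + (1 − γ)/N + γ Σ_{j≠i} Aᵢⱼ Rⱼ/kⱼ

with damping factor γ = 0.85 by default and kⱼ the weighted degree (row
sum) of A. The first term rewards a gene's own main effect, the last
propagates importance along interaction edges, PageRank-style; γ mixes
the two against a uniform baseline. Columns with kⱼ = 0 contribute
nothing; a gene with no contributors at all takes the baseline
Aᵢᵢ/(N·Tr A) + 1/N (this branch only triggers on essentially empty
matrices). If Tr A = 0 the main-effect term is dropped with a warning; an
all-zero matrix yields uniform 1/N scores.

Choices worth stating:

* **Signed matrices are consumed through |A|.** reGAIN off-diagonals carry
  sign, but the kⱼ normalization and the flow interpretation presuppose
  non-negative weights, so CINC uses the element-wise absolute value. The
  signed matrix is kept for the hub decomposition.
* **kⱼ includes the diagonal** (a literal row sum). An exclude-diagonal
  variant is a keyword flag; at N = 100 the difference is a ~1% rescaling
  of each column's outflow.
* **Direct solve, not iteration.** N stays in the thousands at most after
  filtering, so the dense solve is exact and testable; the solution
  residual is checked against 1e−10. A fixed-point iterator from a uniform
  start is kept in the package purely as an independent cross-check.

The decomposition behind the hub scatter plot splits each gene's signed
off-diagonal row into pos(g) = Σ max(A_gj, 0) and neg(g) = |Σ min(A_gj, 0)|;
a *negative hub* has neg > pos and falls below the diagonal of the
pos-vs-neg plot, with the signed diagonal element carried along as the
marker size/colour.

### Significance

Centrality and Relief-F scores have no analytic null, hence two empirical
procedures:

* **Permutation** (default mPerm = 100 for centrality scores, where each
  permutation rebuilds the whole matrix, and 1000 for the cheap per-gene
  scorers): permute the class labels, rescore, and take each gene's 95th
  percentile of its own null array as its threshold; calls use strict
  exceedance. The quantile is the order-statistic (inverted-CDF) form, so
  with mPerm nulls the nominal per-gene rejection rate under exchangeability
  is ⌊0.05·mPerm⌋+1 out of mPerm+1 (≈ 0.059 at mPerm = 100), dialect-free
  and conservative. Only the phenotype vector is permuted; covariates stay
  attached to their samples, so with covariates the test addresses a
  composite null — flagged here deliberately.
* **Gaussian mixture**: a two-component univariate mixture fitted to the
  observed scores by EM (k-means++ initialization, 10 restarts, tolerance
  1e−8, 500 iterations, seeded). The higher-mean component is the
  alternative; a gene is called when its alternative posterior strictly
  exceeds 1/2. If the two fitted means coincide within 1e−6 the score
  distribution is treated as unimodal and nothing is called. Scores enter
  raw (no log transform). The mixture route is much cheaper than
  permutation and more powerful; its false-positive cost appears once the
  score distribution blurs (weak signal, small samples), whereas under
  very clean bimodal separation the mixture boundary can call *fewer*
  false positives than the permutation rule's nominal ~5–6% per-gene
  exceedance.

### Comparators

Relief-F is implemented in its deterministic variant: every sample is an
anchor; its k = 10 nearest hits and misses are found by Euclidean distance
over z-scored genes; each gene accumulates mean miss-difference minus mean
hit-difference, with differences normalized by the gene's observed range.
Random Forest importance and L1-penalized (lasso) logistic regression
delegate to scikit-learn: the forest defaults to 5000 trees with
permutation importance (impurity importance is a flag); the lasso uses
10-fold stratified cross-validation at minimum log loss, z-scored genes,
main-effect terms only, and its exact zero coefficients are read directly
as "not selected" without a significance pass.

## Simulator

The generator emulates case-control microarray data whose co-expression
follows a known network, so every downstream claim can be scored against
ground truth.

1. **Topology.** Scale-free graphs by Barabási–Albert preferential
   attachment (default 1 edge per new node, giving a connected tree with
   pronounced hubs) or Erdős–Rényi graphs with uniform edge probability.
   When the ER probability is not given it is matched to the expected
   scale-free edge count at the same N, holding edge density constant
   across topology comparisons.
2. **Base expression.** An N×M standard-Gaussian matrix; iterating genes
   in index order, each still-unmodified neighbour j of gene i is replaced
   by gene i's row plus Gaussian(0, noise) draws, and never re-modified.
   With unit-variance sources this yields edge correlation
   1/√(1 + noise²) ≈ 0.9988 at noise 0.05 and ≈ 0.32 at noise 3. A
   modified row may itself serve as a later source (correlation decays
   along network paths); `chain=False` disables that.
3. **Differential co-expression attack.** Samples are split half cases,
   half controls (labels fixed before any attack and carried explicitly).
   Each of n target genes — default ⌈0.10·N⌉ — has its case-group values
   randomly permuted within the row. The case mean is exactly preserved
   (same multiset), so the attack creates *no* main effect; it only
   severs the target's correlations with its neighbours inside cases.
4. **Main-effect mode.** Instead of the attack, every gene row is scaled
   to per-gene standard deviation 0.7 (a realistic spread for log2
   intensities of well-expressed genes; scaling preserves all
   correlations) and target genes gain +log2(fold change) in case columns
   — standardized effect log2(FC)/0.7 ≈ 1.43 at a 2-fold change.

What the simulator does **not** model: probe-level artifacts (background,
dye bias, normalization), heavy-tailed or heteroscedastic noise,
correlated attacks, overlapping pathway structure, or confounded designs.
Passing benchmarks here therefore show that a method recovers planted
rewiring under clean Gaussian conditions, not that it survives real
microarray pathologies.

## Benchmark configuration

The replicate study defaults to N = 100 genes, n = 10 targets, M = 40
balanced samples, 20 replicates per condition, noise 0.05 for the
interaction arm and fold change 2 for the main-effect arm, with every
method scored on the same replicate datasets (a paired design that
sharpens method contrasts). The study uses mPerm = 50 permutations per
replicate and, for Random Forest inside the permutation loop, 100 trees
with impurity importance — a forest rebuilt mPerm times per replicate
makes the 5000-tree permutation-importance default disproportionate for a
benchmarking loop, and at N = 100 the impurity ranking is an adequate
stand-in for thresholding purposes. Single-shot API calls keep the larger
defaults. All stages derive their seeds from one root seed via seed
sequences, so studies are bit-reproducible.

## Numerical notes and limitations

* Correlation clamp 1e−7; CINC residual bound 1e−10; EM tolerance 1e−8;
  ridge fallback 0.1 on z-scored predictors.
* Gene ranking breaks score ties lexicographically by gene id so output
  order is deterministic.
* dcGAIN is restricted to dichotomous phenotypes and cannot adjust for
  covariates; reGAIN handles quantitative traits (Gaussian family) and
  covariates but pays for it with per-pair model fits and occasional
  separation fallbacks at small M.
* The lasso comparator deliberately contains no interaction features, so
  it is structurally blind to pure differential co-expression — it serves
  as the negative control for that signal class.
* The univariate filter (`filter_top_probes`) is a convenience for large
  matrices; it is fitted on the same data it filters and is not
  cross-validated, so it should not feed formal inference downstream.
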