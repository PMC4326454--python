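# netgain

Differential co-expression network inference, PageRank-style gene
centrality, and susceptibility-hub discovery for case-control expression
data.

## The problem

Standard differential-expression analysis tests each gene's mean shift
between groups. But disease processes often *rewire* the network instead:
the correlation between two genes present in healthy controls breaks down
in cases, while both genes' means stay put. A gene sitting at the centre
of many rewired edges — a **susceptibility hub** — is invisible to
univariate tests. `netgain` finds such hubs by building a gene-gene
interaction matrix from the data, ranking genes with a network
centrality over that matrix, and calibrating significance empirically.

## The model

Two routes build the N×N **genetic association interaction network**
(GAIN) matrix A, with main effects on the diagonal and pairwise
interaction scores off it:

* **dcGAIN** — the Fisher z-test for a between-group correlation
  difference. With within-group Pearson correlations r¹ᵢⱼ (cases, m₁
  samples) and r⁰ᵢⱼ (controls, m₀), and z(r) = atanh(r):

      Zᵢⱼ = |z(r¹ᵢⱼ) − z(r⁰ᵢⱼ)| / √(1/(m₁−3) + 1/(m₀−3))

  Diagonal: per-gene Welch t-statistics.

* **reGAIN** — per gene pair, a GLM with a multiplicative interaction,
  logit P(D=1|Gᵢ,Gⱼ) = b₀ + bᵢGᵢ + bⱼGⱼ + bᵢⱼGᵢGⱼ (+ covariates); the
  standardized bᵢⱼ is the off-diagonal, the single-gene coefficient the
  diagonal. Handles quantitative traits (Gaussian family) and covariate
  adjustment; all pairs are fitted at once by a batched IRLS solver.

**CINC** (complete interaction network centrality) then ranks genes by
solving

    Rᵢ = Aᵢᵢ/(N·Tr A) + (1 − γ)/N + γ Σ_{j≠i} Aᵢⱼ Rⱼ/kⱼ ,   γ = 0.85

so a gene scores high through its own effect *and* through importance
flowing in from its interaction partners (kⱼ = weighted degree).
Significance comes from label permutation (per-gene 95th-percentile
thresholds) or a two-component Gaussian mixture on the score
distribution. Relief-F, Random Forest importance and the lasso are
included as comparison selectors, and a network-based simulator generates
case-control data with known rewired genes for benchmarking. See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a 100-gene, 40-sample case-control dataset over a scale-free
network where 10 random genes have their case-group values permuted —
correlations to their neighbours are destroyed in cases, means untouched
— then recover them:

```python
from netgain import (SimulationConfig, simulate_dataset, dcgain, cinc,
                     rank_genes, gmm_calls)

sim = simulate_dataset(SimulationConfig(n_genes=100, n_samples=40,
                                        n_targets=10, noise=0.05, seed=42))
gain = dcgain(sim.expression)          # Fisher z-test interaction matrix
result = cinc(gain, gamma=0.85)        # centrality scores
print(rank_genes(result)[:12])
calls = gmm_calls(result.to_series(), seed=0)
print(sorted(calls.significant_genes))
print(sorted(f"g{i}" for i in sim.truth))
```

Output:

```
['g8', 'g78', 'g86', 'g64', 'g20', 'g43', 'g1', 'g53', 'g67', 'g73', 'g66', 'g55']
['g1', 'g20', 'g43', 'g53', 'g64', 'g67', 'g73', 'g78', 'g8', 'g86']
['g1', 'g20', 'g43', 'g53', 'g64', 'g67', 'g73', 'g78', 'g8', 'g86']
```

All ten attacked genes occupy the top ten centrality ranks (top score
0.0356 for `g8` against a 1/N baseline of 0.01), and the mixture
threshold calls exactly those ten significant: 10/10 recovered, no false
positives. None of them would show up in a t-test — the attack preserves
every group mean.

The same workflow is available from the shell:

```sh
netgain simulate --n-genes 100 --n-samples 40 --seed 42 --out-prefix sim
netgain dcgain --expr sim.expr.tsv --pheno sim.pheno.tsv --out gain.tsv
netgain cinc --gain gain.tsv --out scores.tsv
```

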