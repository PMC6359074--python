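# metshift

Condition-contrast analysis of untargeted metabolomics feature tables:
which metabolites discriminate two dietary conditions, and how does the
metabolite *dependence network* rewire between them?

The package is aimed at analysts working with small-n / large-p relative
abundance tables (tens of samples, hundreds of metabolites) from two-condition
designs — the motivating setting is ~350 metabolites over ~31 *Drosophila*
larval samples split across a normal diet (ND) and a high-fat diet (HFD),
with genotypes classed by their triglyceride reaction norm. It provides:

- **Preprocessing** — minimum-detected-value imputation of left-censored
  cells, log transform, robust-z outlier scoring (`metshift.io`).
- **Random-forest discrimination** — bagged CART forests with out-of-bag
  (OOB) error, OOB tuning of the per-split candidate count *mtry* over a
  grid, permutation importance (mean decrease in OOB accuracy, raw and
  SD-scaled), and Ward clustering of the top metabolites (`metshift.forest`).
- **Gaussian graphical models** — two-step nodewise-Lasso selection suited
  to n ≪ p: a Lasso-path-derived family of candidate graphs, scored by a
  penalized RSS criterion with penalty scalar `K` and degree cap `dmax`,
  plus the (K, dmax) sweep with plateau detection (`metshift.ggm`).
- **Network comparison** — edge symmetric difference (esd), Pearson
  correlation networks with edge-count-matched thresholds, correlation
  cutoff p-values, and three-way edge-conservation decomposition
  (`metshift.compare`).
- **Univariate statistics** — per-metabolite two-way ANOVA (Type-II),
  triglyceride regression, the 25%-rule reaction-norm classifier, PCA
  (`metshift.stats`).
- **Synthetic data** — a generator that emulates the study design with
  known ground truth (condition graphs, planted differentiators), for
  power analysis and recovery testing (`metshift.simulate`).

## The statistics at the core

**Gaussian graphical model (GGM).** An edge (a, b) means metabolites a and b
are dependent *conditional on all others* (nonzero partial correlation).
Selection is two-step: (1) for each node a, the Lasso regularization path of
a on all other variables yields candidate neighborhoods — the first
`dmax` variables to enter the path; candidate graphs are assembled with the
conservative AND rule (edge kept only if each endpoint selects the other).
(2) The family member minimizing

```
Crit(G) = Σ_a RSS_a(G) · (1 + pen(d_a) / (n − d_a)),
pen(d)  = K · d · (1 + √(2·log(p−1)))²
```

is selected, where RSS_a(G) is the residual sum of squares of regressing a
on its neighbors in G and d_a its degree. K ∈ [2, 5] controls sparsity
(larger K, fewer edges); `dmax` caps the node degree.

**Edge symmetric difference.** For edge sets E(HF), E(N):

```
esd = ( |E(HF)\E(N)| + |E(N)\E(HF)| ) / ( |E(HF)| + |E(N)| )
```

the proportion of edges not shared: 0 for identical networks, 1 for
disjoint ones.

**OOB permutation importance.** Per tree, the OOB accuracy drop after
shuffling one metabolite's values among that tree's out-of-bag samples;
averaged over trees (raw) and divided by its standard error (scaled).

## Worked example

```python
import pandas as pd
import metshift as ms

spec = ms.SyntheticSpec(seed=1)              # study-emulating defaults
table, meta, truth = ms.sample_table(spec)   # 31 x 350, 1050 censored cells
logged, report = ms.impute_min_and_log(table)

diet = pd.Series({m.sample_id: m.diet for m in meta}).loc[logged.sample_ids]
fit = ms.fit_forest(logged, diet, ms.RfConfig(ntree=1000, mtry_selected=18, seed=1))
print(fit.oob_error, fit.per_class_error)
# 0.0 {'HFD': 0.0, 'ND': 0.0}

imp = ms.permutation_importance(fit)
print(list(imp.index[:3]))
# ['diet_marker_009', 'diet_marker_007', 'caprylate_analog']

res = ms.esd(truth.graph_hfd, truth.graph_nd)
print(res.value, res.shared)
# 0.7866666666666666 16

print(ms.correlation_pvalue(0.9235, 31))
# 1.3539476666504229e-13
```

The forest's OOB error is its built-in test error (no validation split
needed); the importance ranking surfaces the planted medium-chain
fatty-acid analogs; the esd of 0.787 says the two condition networks share
only 16 of 150 edges; and the p-value is the two-sided significance of a
Pearson correlation of 0.9235 at n = 31.

Narrative scripts, one per capability, live in `examples/`; a thin CLI
(`metshift simulate|rf|ggm|ggm-sweep|compare|stats`) wraps the same calls
for shell use.

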