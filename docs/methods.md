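# Methods

## Setting and data model

The package analyses relative-abundance tables from untargeted
metabolomics: n samples (rows) by p metabolites (columns), nonnegative
reals with missing cells where a compound fell below the detection limit.
The motivating design is small-n / large-p: ~31 samples (16 normal-diet,
15 high-fat-diet) over 16 genotypes, ~350 metabolites. Inputs are assumed
already normalized to an internal protein standard by the measurement
vendor; that normalization is not re-implemented.

## Preprocessing

Missing cells are treated as left-censoring and imputed to the minimum
*observed* value of that metabolite across retained samples, then the whole
table is log-transformed (natural log by default; log2/log10 available).
Minimum-value imputation is the standard treatment when missingness is
detection-limit driven; it is deliberately not a model-based imputation, and
a metabolite with no observed value at all is an error, not a guess.

Outlier screening formalizes "a sample whose concentrations are abnormally
high": each sample is scored by the robust z of its median log abundance
(median/MAD across samples, scale 1.4826·MAD; when MAD is zero, any
deviation scores infinite). The default cutoff is 5 robust SDs. Nothing is
removed automatically — removal is an explicit caller action — because on
31 samples a silently dropped sample changes every downstream number.

## Random forest

Classical bagged CART: each of `ntree` (default 1000) trees is grown to
purity on a bootstrap resample, with `mtry` random candidate features per
split (Gini impurity). The individual trees are sklearn CART estimators;
the bagging loop, OOB bookkeeping, importance and tuning are implemented in
the package so that every OOB quantity is explicit.

- **OOB error** — each sample is predicted by majority vote over only the
  trees whose bootstrap excluded it; the error over these votes is the
  forest's internal test error, so no validation split is spent.
- **mtry tuning** — one forest per grid value (default grid 5, 18, 100,
  250, 350), seeded from a common base seed plus the grid position; ties in
  OOB error break toward the value nearest floor(√p), the classical
  default.
- **Permutation importance** — per tree, OOB accuracy minus OOB accuracy
  after permuting one metabolite's values among that tree's OOB samples;
  the per-tree decreases are averaged (raw) and divided by their standard
  error over trees (scaled). Rankings use the scaled variant; both are
  reported. Features a tree never splits on contribute exact zeros, which
  the implementation exploits for speed.
- **Phenotype contrast** — reaction-norm analyses use only the two extreme
  classes (N>HF vs N<HF); the no-change class is excluded via a labeled
  subset operation.
- No class balancing is applied; per-class error rates are reported as-is.

OOB error is reported for the forest actually grown; with a randomized
algorithm the value is reproducible only for a fixed seed, and error rates
across seeds agree in distribution.

## Gaussian graphical model selection

Suited to n ≪ p, the estimator is the two-step nodewise-Lasso scheme:

1. **Family construction.** For each node a, the Lasso path of a on all
   remaining columns (100 log-spaced penalties from the per-node null knot,
   sklearn coordinate descent) is scanned for entry order; the first
   `dmax` entrants are a's candidate neighbors. Candidate graph h
   (h = 0..dmax) joins a and b when each lies in the other's first h
   entries (AND rule; OR available behind a flag). Because per-node
   prefixes are nested in h, the family is an increasing chain of at most
   dmax+1 graphs, always containing the empty graph. This shared-index
   assembly avoids the exponential product of per-node candidate sets.
2. **Scoring.** Each family member is scored by
   `Crit(G) = Σ_a RSS_a(G)·(1 + pen(d_a)/(n − d_a))` with
   `pen(d) = K·d·(1 + √(2·log(p−1)))²`, and the minimizer is selected;
   ties break toward fewer edges, then the lexicographically smallest edge
   set, so selection is deterministic.

**Why this penalty.** Under the null, the first variable to enter a node's
Lasso path is approximately the maximum of ~p−1 squared correlations, i.e.
a χ²(1) maximum of size ~2·log(p−1). A penalty of that same order (the
plain `K·d·log(p−1)`, kept available as `penalty="log"`) admits a handful
of spurious edges even at n = 1000; the default multiplies in the
`(1+√(2·log(p−1)))²` complexity factor familiar from penalized model
selection over p candidates, which dominates the null maximum. Measured
behavior with the default at K = 2, p = 30, n = 1000: column-permuted data
select 0 edges; chain and capped random graphs are recovered with edge
F1 ≈ 1.0; edge counts are non-increasing in K and plateau once dmax
exceeds the true maximum degree. Columns are always standardized before
regression (centering-only available); graphs are reported on metabolite
names.

K is conventionally in [2, 5] (values outside warn, not error); dmax
defaults to 5. The `sweep_k_dmax` grid reports edge counts and the per-K
dmax plateau, the diagnostic used to fix dmax.

At the study scale itself (n ≈ 15–31 per condition) the selector is
honest about identifiability: with the generator's default partial
correlations (≈0.35) a per-condition fit returns few or no edges, because
a single neighbor must explain a large RSS fraction to beat the penalty at
n = 15. Real metabolomics tables carry far stronger pairwise correlations
(the motivating dataset supports a |r| > 0.92 network of >100 edges), which
is what makes sparse GGM selection productive there. Published per-condition
edge counts are therefore not a reproduction target; the recovery and null
properties above, at sizes where the structure is identifiable, are.

## Network comparison

- **esd** — (|A\B| + |B\A|)/(|A| + |B|) on edge sets; weights ignored;
  undefined (error) only when both sets are empty. Symmetric, in [0, 1],
  0 iff equal, 1 iff disjoint.
- **Correlation network** — edge iff |Pearson r| *strictly* exceeds the
  threshold; weights carry r. Edge-count matching sorts all pairwise |r|
  descending and returns the (target+1)-th largest as the cutoff, so
  exactly `target` pairs exceed it generically; under boundary ties the
  nearest achievable count is returned, preferring the larger (matching a
  129-edge target can land on 130).
- **Cutoff significance** — two-sided p from t = r·√((n−2)/(1−r²)) on
  n−2 df; |r| = 1 reports p = 0 with a degeneracy warning. At the
  motivating cutoff, r = 0.9235 with n = 31 gives p = 1.354e-13.
- **Three-way conservation** — the 7 exclusive regions of the HFD, ND and
  complete-data edge sets; per union edge, Pearson r within each dataset
  (pairwise-complete), flagging edges whose member dataset does not carry
  the highest |r|.

## Univariate layer

Per metabolite: fixed-effects two-way ANOVA on log abundance with diet,
reaction-norm class and their interaction, using Type-II sums of squares
because the genotype design is unbalanced (Type-I would make term order
matter); Welch t post hoc between the extreme reaction-norm classes; OLS
against triglyceride level with signed r. Raw p-values are always
accompanied by Benjamini–Hochberg q-values — raw p < 0.05 sets remain
available for importance-vs-significance overlap reports, but no claim is
made on raw p alone. The 25% rule classes a genotype N_lt_HF when its
high-fat triglyceride exceeds the normal-diet value by ≥25%, N_gt_HF for
the reverse, zero otherwise (boundary inclusive). PCA is centered and, by
default, scaled (correlation PCA), the appropriate choice for abundances
spanning scales.

## Synthetic generator

`SyntheticSpec` defaults encode the emulated study:

| parameter | default | meaning |
|---|---|---|
| p | 350 | metabolites |
| n_nd / n_hfd | 16 / 15 | samples per diet (one high-fat sample short, as after outlier removal) |
| edges_nd / edges_hfd | 57 / 93 | true condition-graph sizes |
| target_esd | 0.786 | requested edge symmetric difference |
| max_degree | 5 | degree cap of true graphs |
| partial_corr_magnitude | 0.35 | absolute partial correlation of true edges (capped) |
| differentiator_size / shift | 10 / 2.5 SD | diet-shifted block (medium-chain fatty-acid analogs) |
| phenotype_block_size / corr / shift | 7 / 0.6 / 2.0 SD | correlated dipeptide-analog block, elevated in the N>HF class |
| n_genotypes | 16 | 6 / 5 / 5 across N<HF / zero / N>HF classes |
| detection_floor_quantile | 0.1 | per-metabolite lower-tail censoring |

Mechanics: the two condition graphs share exactly s edges, with s the
feasible integer making (|E₁|+|E₂|−2s)/(|E₁|+|E₂|) nearest the requested
esd — so the realized esd is exact by construction (57/93 edges at target
0.786 give s = 16, esd = 118/150 ≈ 0.787). Each graph becomes a precision
matrix with unit diagonal and edge entries of random sign scaled by
1.2× the larger endpoint weighted degree (strict diagonal dominance, hence
positive definiteness, with support exactly the graph); entries are
additionally capped at the requested partial-correlation magnitude so
isolated edges are not artificially strong. Latent log abundances are
multivariate normal with covariance the inverse precision; the
differentiator block is mean-shifted under HFD; the phenotype block gains a
shared within-block factor (inducing the requested within-block
correlation) plus a class shift; values are exponentiated to abundance
scale and each metabolite's lowest detection-floor fraction is censored to
missing. All randomness flows from a single explicit seed; no global state.

Effect-size calibration: the source design reports no effect sizes, so the
two shifts were fixed once against the error scales the emulation targets —
2.5 SD on the differentiators puts the diet forest at 0–2 OOB errors of 31
(observed 3.2% with class errors 0.0/0.06 at the first measurement), and
2.0 SD (diluted by the within-block factor) puts the extreme-class
phenotype contrast at a moderate 20–45% OOB error, clearly worse than diet
and better than chance. Genotype random intercepts are off by default:
genotype and sample are confounded in the emulated design, so the null
generator stays simple.

What the generator does *not* emulate: batch effects, chromatographic or
ionization artifacts, heteroscedastic technical noise, the heavy-tailed
marginal correlation structure of real metabolomics tables (real data show
|r| > 0.9 pairs by the hundred; the generator's marginals are tied to its
sparse precision matrices). Tests passing on synthetic data therefore
validate the estimators' correctness and their behavior under the study's
sampling design, not the biological conclusions one would draw from real
tables.

## Numerical choices and degenerate inputs

- Lasso paths: 100 log-spaced penalties, path entry detected at |coef| >
  1e-10, entry ties broken by absolute correlation with the response.
- Nodewise regression requires n ≥ 3; dmax ≥ n−2 warns and caps
  neighborhoods at n−3; a node degree reaching n errors (no residual df).
- Zero-variance columns are excluded with a warning in GGM and correlation
  networks; constant columns in forests get exactly zero raw importance.
- Imputation requires strictly positive observed values (log undefined
  otherwise).
- Edge identity is exact, case-sensitive name match after trimming
  whitespace; mismatched vocabularies warn with the offending names.
- Missing tokens in tables: empty cell or "NA", configurable.
- Problem sizes in the test and acceptance runs (study-scale tables of
  31×350; recovery problems of p = 30, n = 1000, 20 seeds; 500–1000-tree
  forests) were chosen as the smallest at which the distributional claims
  are stable.

## Known limitations

- The selection penalty is this package's concrete instantiation of the
  two-parameter (K, dmax) scheme; other members of that family (e.g.
  inverse-chi-square quantile constructions) will select slightly different
  graphs on the same data, so published edge counts from other tools are
  approximate references, not equalities.
- AND-rule symmetrization is conservative; dense hub structures may be
  under-recovered at small n. The OR rule is available but inflates false
  positives.
- OOB error on 31 samples is quantized at 1/31 ≈ 3.2%; comparisons across
  runs should use error counts, not percentages.
- The two-way ANOVA treats genotype as exchangeable replication; a
  mixed-effects genotype model is out of scope.
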