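# Methods

`smrnet` reimplements, as a tested pipeline over synthetic data, a spatial
analysis of provincial Alzheimer's-disease mortality: standardized mortality
ratios are computed per province-year, predicted from environmental and
socio-economic indicators with linear and random-forest models under
repeated cross-validation, screened with an all-relevant feature selector,
cross-checked with a province similarity network, and explained globally
(impurity importance) and locally (Shapley values).

## Standardized mortality ratio (smrnet.smr)

Indirect standardization: for province *m*,

    SMR_m = O_m / E_m,        E_m = Σ_i R_i n_i,        R_i = M_i / N_i,

where `O_m` is the observed death count, `n_i` the province population in
age class *i*, and `M_i`, `N_i` the reference (national) deaths and
population per age class. SMR > 1 means mortality in excess of the
reference. Each year is standardized independently — the analysis is
purely spatial and applies no temporal smoothing. `E_m = 0` is treated as a
hard error (an empty province), never as an infinite SMR. No confidence
intervals are attached to the SMR; they are outside this pipeline's scope.

## Synthetic data (smrnet.synth)

The generator emulates the structure the analysis assumes rather than any
real geography:

* **Panel.** 107 provinces × 31 indicators × 5 years (2015–2019), the
  indicators grouped into five categories (Air Pollution, Soil Pollution,
  Urban Environment, Socio-economic, Other Pathologies). Indicators load on
  K = 5 latent province factors with weight `sqrt(indicator_correlation)`
  (default 0.3), the remainder being independent noise, so one knob
  controls the within-group correlation. Values are stationary across
  years up to i.i.d. noise of sd `noise_sd` (default 0.2), matching the
  assumption that spatial distributions do not change over the window.
  Indicators are kept on a standardized scale; no attempt is made to mimic
  real pollutant units.
* **Planted effects.** `effect_spec` maps indicators to `(coefficient,
  form)` on the log mortality-rate scale, with forms `linear` (`c·z`),
  `threshold` (`c·(1[z > median] − ½)`, an exceedance response), and
  `quadratic` (`c·(z² − 1)`), all centered so the SMR stays centered near
  1. Defaults plant o3 (0.4, linear) and no2 (0.8, threshold) — equal
  strength on the log scale, since a centered threshold effect has sd
  `c/2` — and circulatory-disease mortality at (−0.25, linear), emulating
  the negative comorbidity association expected when a competing cause of
  death precedes dementia death.
* **Mortality.** 18 five-year age classes. Reference rates are log-linear
  in class index (slope 0.5/class) and calibrated to a crude rate of
  4·10⁻⁴, roughly the Italian crude Alzheimer's mortality, which puts
  provincial expected counts in the tens-to-hundreds. Province populations
  are lognormal (median 400k, σ = 0.6) with a declining age profile.
  Observed deaths are `Poisson(E_m · exp(η))` with `η` the planted
  predictor plus `N(0, noise_sd²)` noise, so the true log-SMR equals the
  planted predictor in expectation and the zero-effect, zero-noise
  configuration yields SMR concentrated at 1 (verified in the tests).
* **Missingness** is MCAR at rate `missing_rate` (default 5%), injected as
  a separate seeded operation. No mechanism beyond MCAR is modelled; the
  real data's missingness pattern is unknown.

All randomness flows from a single master seed through fixed per-operation
streams, so each stage is independently reproducible.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring provinces, real pollutant distributions or units, non-random
missingness, and temporal trends. Passing tests therefore demonstrate the
pipeline's correctness and its recovery behaviour under the planted
mechanism, not conclusions about real Italian data.

## Preprocessing (smrnet.preprocess)

Missing cells are filled with the mean of the observed values of the same
indicator in the same year, across all provinces — a global preprocessing
step applied before cross-validation, reproducing the protocol's order of
operations. This leaks a small amount of fold information; the stricter
within-fold variant was considered and deliberately not made the default,
to match the protocol. Imputation is idempotent and mean-preserving. No
scaling is applied to the features: the forest is scale-invariant and the
linear model's coefficients are not interpreted.

## Feature selection (smrnet.boruta)

A from-scratch Boruta: each run appends an independent row-permutation
("shadow") of every feature, fits a bagged forest of regression trees, and
computes per-column Z-scores as the mean over trees of the out-of-bag
accuracy loss (increase in OOB MSE after a single permutation of the
column) divided by its standard deviation across trees. A feature scores a
hit when its Z exceeds the maximum shadow Z (MZSA). Hits over M runs are
Binomial(M, ½) under the null; after every run a two-sided binomial test at
a Bonferroni-corrected α = 0.05 (corrected across the original feature
count) confirms or rejects features. Rejected features are dropped from
later runs; confirmed features stay in the forest as competition; features
still tentative when the budget (default M = 100) is exhausted are **not**
selected. No "rough fix" of tentatives is applied.

The selection forest defaults to 200 trees with `ceil(p/3)` candidate
features per split over the augmented (originals + shadows) matrix. The
operating-characteristics study uses 500 trees: confirmation power rises
with tree count (the Z standard error shrinks while MZSA does not) and
saturates around 500 on this design. Note the run count M here is a
different quantity from the 600 trees of the prediction forest.

## Models and evaluation (smrnet.models)

* **Linear benchmark**: ordinary least squares with intercept;
  rank-deficient designs are an error.
* **Random forest**: 600 trees, `F = ceil(S/3)` candidate features per
  split (the protocol's F = S/3, rounded up), trees grown to full depth
  with ≥1 sample per leaf, bootstrap sampling, mean-decrease-impurity
  importances (summing to 1 per fit). Backed by scikit-learn.
* **Evaluation**: 5-fold cross-validation with a fresh random partition
  per repeat. The full protocol uses 100 repeats; the bundled studies use
  10 (the across-repeat spread stabilizes well before that at n = 107).
  Per-repeat error is the fold-mean of the out-of-fold MAE
  `(1/n) Σ|A_i − P_i|`; the predicted-vs-actual association is the Pearson
  correlation of pooled out-of-fold predictions with a two-sided p-value.
  The ± reported with MAE is the standard deviation over repeats.
* **Selection inside CV**: with `use_boruta`, the selector runs on each
  training fold only and the forest uses the confirmed features;
  unconfirmed features score 0 importance in that fit. If a training fold
  confirms nothing, the fit falls back to all features (counted and
  reported). A feature is "selected for a year" when confirmed in more
  than half of the repeat × fold runs.

## Province network (smrnet.network)

Provinces are compared by `d_ij = |Spearman ρ|` between their 31-long
indicator vectors (average ranks on ties; a constant vector is an error).
The absolute value makes strongly anti-correlated provinces maximally
similar — implemented as specified, with the caveat noted. Ranks are taken
over raw indicator values; an optional per-indicator standardization is
available since mixed units would make within-province ranks
scale-sensitive (the default synthetic indicators share a scale).

Hard thresholding: `c_ij = 1` iff `d_ij ≥ th`, `i ≠ j`. The threshold is
chosen to maximize the Shannon entropy of the betweenness distribution.
Betweenness values are normalized to a probability distribution before the
entropy is taken — the raw −Σ b log₂ b is not scale-free and would be
dominated by the node count; this normalization is a deliberate
interpretation. `0·log 0 ≡ 0`, and an all-zero betweenness vector has
entropy 0. Candidate thresholds default to all distinct off-diagonal
similarities (exhaustive over realizable networks); the pipeline uses a
101-point uniform grid at n = 107, where the exhaustive scan (~5 700
candidates) is needlessly slow. Ties break toward the smallest threshold,
i.e. the densest maximizing network.

Centrality features: degree `k_i = Σ_j c_ij`; Freeman betweenness (via
networkx, validated against a brute-force all-pairs BFS oracle); closeness
in the Wasserman–Faust convention — computed within a node's component and
scaled by `(n_c − 1)/(N − 1)`, so disconnected graphs need no infinity
convention and isolated nodes get 0; eigenvector centrality as the
principal eigenvector of C, nonnegative, unit Euclidean norm, computed by
power iteration on `C + I` from a uniform start with 1e-10 tolerance (the
identity shift preserves eigenvectors while preventing the sign
oscillation of bare power iteration on bipartite graphs). An edgeless
graph yields the zero vector. On disconnected graphs the iteration selects
the component with the largest spectral radius.

The four centralities are appended to the 31 indicators as a robustness
check: the model's cross-validated error should not shift by more than the
across-repeat MAE spread.

## Shapley attribution (smrnet.explain)

Both routines use the interventional convention `f_x(F) = mean_z f(x_F,
z_{∖F})` over a background matrix (the training fold, subsampled to a cap —
30–100 rows in the bundled studies). `shap_exact` enumerates all subsets
with the factorial weights `|F|!(|S|−|F|−1)!/|S|!` (feasible to 15
features) and is the oracle. `shap_fast` is a polynomial-time algorithm
for tree ensembles: per tree and background row the coalition game is a
sum of leaf indicator games, whose Shapley values have the closed form
`(|U|−1)!|V|!/(|U|+|V|)!` for features only the explained sample satisfies
(U) and `−|U|!(|V|−1)!/(|U|+|V|)!` for features only the background row
satisfies (V); leaves with a path feature satisfied by neither are
unreachable and contribute nothing. The sum over leaves telescopes to
`f(x) − f(z)`, so efficiency holds exactly; agreement with the enumeration
oracle is at machine precision and asserted to 1e-6 in the tests.

SHAP values are computed only on out-of-fold samples, so over R repeats
each province accumulates R values whose mean is reported; features are
ranked by mean |SHAP| across provinces. The per-repeat aggregation scheme
(mean, out-of-fold, training-fold background) is this package's own
convention.

## Study designs and problem sizes (smrnet.studies)

* **Null calibration**: zero effects, zero noise; mean SMR within 3
  standard errors of 1.
* **Selection operating characteristics**: 5 indicators planted with
  equal exceedance (threshold) effects, coefficient 0.8, among 26
  independent noise indicators; noise_sd 0.1; 20 seeds, M = 50 runs,
  500-tree selection forests. Exceedance effects are used because they are
  bounded (the SMR cannot collapse to zero under a deep negative tail) and
  each is captured by a single split, making "informative" unambiguous;
  with 5 equal **linear** effects each feature's marginal correlation is
  combinatorially pinned near 1/√5 ≈ 0.45 and forest-importance masking
  between chance-correlated planted features caps confirmation power
  below 0.9 regardless of forest size — a regime that measures masking,
  not the selector's error control. Independent indicators make any
  non-planted confirmation a genuine false positive (with correlated
  indicators, proxies of a planted feature are legitimately
  "all-relevant").
* **Model comparison**: both drivers planted as threshold effects
  (coefficient 0.8) plus the negative comorbidity; 10 CV repeats;
  selection inside CV scaled to M = 25 runs with 200-tree forests.
* **Driver recovery**: the default generator configuration; 1 CV repeat,
  200-tree forests, 30-row SHAP backgrounds, 20 seeds; both drivers must
  rank top-3 by mean MDI and mean |SHAP| and the comorbidity's SHAP-value
  correlation must be negative.
* **Network robustness**: default configuration, 10 repeats, 101-point
  threshold grid.

## Numerical conventions and degenerate inputs

Z-scores with zero across-tree spread are 0. Shadow columns of constant
features are constant (hits impossible). The forest's MDI vector sums to 1
per fit; when selection masks features the mean importance still sums to 1
over fits. `spearman_abs_matrix` requires ≥3 indicators and non-constant
province vectors. Tie-breaks: threshold scan → smallest threshold;
rankings → descending sort order (stable). All CSV output is plain text;
the pipeline manifest records seeds and SHA-256 hashes of every output so
reruns can be verified byte-for-byte.

## Known limitations

* The entropy objective often selects very dense networks on weakly
  structured similarity matrices (near-uniform small betweenness spreads
  entropy over many nodes); this is the objective's honest behaviour, not
  a bug.
* Mean imputation before CV leaks fold information (kept for protocol
  fidelity; a flag enables the stricter variant).
* The MAE formula is implemented literally as the arithmetic mean of
  absolute errors; the protocol's name for it ("root mean absolute
  error") contains no root.
* Boruta run counts, significance level (0.05, Bonferroni) and
  tentative-handling are conventions of this package, stated in the
  selection report; the source protocol does not fix them.
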