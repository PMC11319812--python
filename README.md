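# smrnet

Spatial modelling of provincial disease mortality from environmental and
socio-economic indicators. The package implements, as a tested pipeline
over synthetic data, the full analysis chain used to study provincial
Alzheimer's-disease mortality in relation to pollution: standardized
mortality ratios, all-relevant feature selection, random-forest prediction
under repeated cross-validation, an entropy-thresholded province
similarity network as a robustness check, and Shapley-value attribution.
It is aimed at epidemiologists and methodologists who want each stage of
such a pipeline as a reusable, independently tested building block.

## The statistics at the core

**Standardized mortality ratio** (indirect standardization). For province
*m*: SMR = O_m / E_m with E_m = Σᵢ Rᵢ nᵢ and Rᵢ = Mᵢ / Nᵢ, where O_m is
the observed death count, nᵢ the province population in age class *i*,
and Mᵢ, Nᵢ the reference-population deaths and population by age. SMR > 1
means mortality above the reference.

**Boruta feature selection.** Each feature competes against a permuted
"shadow" copy of itself inside a random forest; a feature scores a hit in
a run when its importance Z-score exceeds the maximum shadow Z-score, and
accumulated hits are tested against Binomial(M, ½). Only features whose
hits significantly exceed M/2 are selected.

**Prediction.** SMR is regressed on 31 provincial indicators with an OLS
benchmark and a 600-tree random forest (⌈S/3⌉ features per split) under
5-fold cross-validation with repeated random partitions; performance is
the out-of-fold mean absolute error and the Pearson correlation of pooled
out-of-fold predictions.

**Province network.** Provinces are linked when the absolute Spearman
correlation of their indicator vectors exceeds a threshold chosen to
maximize the Shannon entropy of the betweenness-centrality distribution;
degree, betweenness, closeness and eigenvector centrality are then
appended to the indicator set to check the model's robustness to added
spatial features.

**Attribution.** Global importance is mean decrease in impurity; local
attribution uses interventional Shapley values, computed exactly for tree
ensembles by a closed-form leaf decomposition and validated against
brute-force subset enumeration.

A synthetic-data module generates the full study structure — 107 provinces
× 31 indicators × 5 years with planted pollutant effects, a negatively
associated comorbidity, latent-factor indicator correlation, age-stratified
mortality and MCAR missingness — so every stage is testable without any
data download. See `docs/methods.md` for models, parameters and design
choices.

## Worked example

```python
import numpy as np
from smrnet import boruta, models, preprocess, smr, synth

cfg = synth.SyntheticConfig(seed=0)          # 107 provinces, 31 indicators
panel = synth.generate_panel(cfg)
mortality = synth.generate_mortality(cfg, panel)
table = smr.compute_smr_table(mortality)     # province-year SMR
panel = preprocess.impute_mean(synth.inject_missing(panel, 0.05, cfg.seed))
X, y, names = preprocess.assemble(panel, table, year=2015)

ev = models.repeated_cv(X, y, "rf", feature_names=names, repeats=10, seed=0)
print(f"RF MAE {ev.mae_mean:.3f} +/- {ev.mae_sd:.3f}, r = {ev.pearson_r:.3f}")
```

prints

```
RF MAE 0.401 +/- 0.013, r = 0.685
```

an out-of-fold mean absolute SMR error of about 0.4 with a strong
predicted-vs-actual correlation — the planted o3, no2 and circulatory-
mortality effects make the synthetic SMR genuinely predictable. The
numbered drivers under `analysis/` walk through the full study:

```
01_simulate_data.py      synthetic panel + age-stratified mortality
02_compute_smr.py        SMR table and the null calibration (mean SMR ~ 1)
03_feature_selection.py  Boruta decisions and operating characteristics
04_model_comparison.py   LM vs RF vs RF+Boruta under repeated CV
05_network_robustness.py entropy-thresholded network + centrality check
06_explain_drivers.py    MDI and SHAP driver recovery
07_full_pipeline.py      everything in one run directory
```

`analysis/04_model_comparison.py`, for instance, reports

```
LM          MAE 0.473 +/- 0.035
RF          MAE 0.362 +/- 0.013
RF + Boruta MAE 0.350 +/- 0.010
RF pooled out-of-fold r = 0.746 (p = 8.74e-191)
```

reproducing the expected ordering: the forest beats the linear benchmark
on nonlinear (exceedance-type) planted effects, and feature selection
trims the noise indicators to improve the forest further.

A `smrnet` command-line umbrella wraps the same stages
(`smrnet simulate | smr | preprocess | select | fit | network | explain |
pipeline`); run any subcommand with `--help`.

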