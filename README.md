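# ccre — climate-contrast resurrection ecology toolkit

`ccre` relates per-species **trait change** (log ratios of paired
historic/modern cohort means, with delta-method sampling variances) to
per-site **climate change** (twelve metrics derived from daily weather
series) using variance-weighted random-effects meta-regression and
all-subsets AICc multi-model inference. The key property of the design:
a uniform storage/maternal bias in the historic cohorts shifts only the
*elevation* of the climate–trait regression, never its *slope* — the
package verifies this invariance end to end.

A synthetic-data layer generates paired daily climate windows (AR(1)
temperature with seasonal cycle, zero-inflated Gamma precipitation) and
paired trait cohorts with known ground truth, so every stage is testable
without any external data.

## Modules

| module | contents |
|---|---|
| `ccre.synth` | paired climate-window simulator, trait-cohort simulator, per-species config sampling |
| `ccre.climate_metrics` | the 12 metrics (means, CVs, ranges, seasonal precipitation extremes, Tetens VPD, excess-heat-factor heatwave / VPD dry-spell / precipitation drought durations), change scalings, collinearity screen |
| `ccre.effect_sizes` | cohort summaries, lnRR + sampling variance, iWUE, overall per-species change |
| `ccre.meta_regression` | from-scratch weighted meta-regression (REML / ML / FE via Fisher scoring), Wald inference, pseudo-R², ML log-likelihoods for information criteria |
| `ccre.model_selection` | AICc, all-subsets enumeration, Akaike weights, importances, model-averaged coefficients, importance matrix |
| `ccre.leaf_economics` | iterative-PCA imputation, PCA, Horn's parallel analysis, component-score responses |
| `ccre.pipeline` | orchestration, ancillary OLS regressions, CSV bundle + manifest |

## CLI

```bash
ccre simulate  --config cfg.yaml --seed 1 --out out/     # synthetic inputs + truth
ccre climate   --historic-csv h.csv --modern-csv m.csv \
               --historic-date 1984-03-15 --modern-date 2019-03-15 --out out/
ccre effects   --measurements-csv traits.csv --out out/  # lnRR table
ccre pairwise  --config cfg.yaml --seed 1 --out out/     # trait vs mean climate
ccre select    --config cfg.yaml --seed 1 --out out/     # all-subsets AICc
ccre economics --config cfg.yaml --seed 1 --out out/     # PCA axis
ccre run-all   --config cfg.yaml --seed 1 --out out/     # everything + manifest
```

Daily climate CSVs have columns `date,tmean_c,precip_mm,rh_pct[,vpd_kpa]`
(ISO dates, contiguous days); trait tables are tidy
`species,era,trait,value` with `era` in `{historic, modern}`. The YAML
config mirrors the `RunConfig` / `ClimateSimConfig` / `TraitSimConfig` /
`ClimateConfig` dataclasses; every analytic constant (extreme-index
windows and percentiles, duration offset, imputation rank, …) is a
config key and is echoed in the run manifest.

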