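{
  "alpha": 0.05,
  "climate_constants": {
    "drought_agg_days": 30,
    "drought_percentile": 10.0,
    "duration_offset": 1.0,
    "ehf_accl_days": 30,
    "ehf_min_run": 3,
    "ehf_percentile": 95.0,
    "ehf_window": 3,
    "month_window_days": 30,
    "n_years": 5,
    "season_months": 4
  },
  "explained_pct": [
    52.871971,
    23.675825,
    23.452204
  ],
  "horn_retained": 1,
  "impute_rank": 1,
  "method": "REML",
  "n_species": 20,
  "pca_scaled": false,
  "per_trait_k": {
    "leaf_area": 19
  },
  "scalings": {
    "max_drought_dur": "log_ratio",
    "max_dryspell_dur": "log_ratio",
    "max_heatwave_dur": "log_ratio",
    "max_seasonal_precip": "log_ratio",
    "mean_precip": "log_ratio",
    "mean_temp": "difference",
    "min_seasonal_precip": "log_ratio",
    "precip_range": "log_ratio",
    "precip_var": "log_ratio",
    "temp_range": "difference",
    "temp_var": "difference",
    "vpd": "log_ratio"
  },
  "seed": 2024,
  "trait_sim": {
    "alpha": 0.0,
    "delta": 0.0,
    "seed": 2025,
    "slopes": {
      "max_heatwave_dur": 0.1,
      "mean_temp": 0.05
    },
    "tau": 0.03
  },
  "version": "0.1.0"
}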