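{
  "n_tested": 396,
  "plp_prevalence_pct": 0.75,
  "vus_prevalence_pct": 1.77,
  "plp_mean_age": 60.7,
  "plp_age_range": [56, 64],
  "vus_mean_age": 45.2,
  "vus_age_range": [38, 57]
}
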