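seed: 3
cohort:
  n: 12
  n_test: 2
  p_incline20: 0.5
  p_large: 0.5
  grid: {shape: [64, 64, 64], spacing_mm: [3.75, 3.75, 3.75]}
groups:
  - {label: het3, size: 3, match_policy: none}
segmenter:
  mode: mas
  n_test_cases: 2
mas:
  demons: {levels: 2, iterations_per_level: 20}
metrics: {centre_mode: own}
rules: {threshold_cm: 0.3}
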