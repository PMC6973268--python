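# Benchmark setting 2: case-mix and beyond-case-mix heterogeneity that
# compensate each other, leaving five nearly equal marginal relative risks.
# The per-trial treatment main effects beta_1k differ across trials (the
# source table's trial-indicator labels for the 4th and 5th terms are
# obvious typos, corrected to S=4 and S=5; the correction is confirmed by
# the Monte-Carlo truth check against the reported diagonal relative risks).
name: setting2
n_total: 3750
n_trials: 5
covariates: [L1, L2, L3, L4, L5]
covariate_law:
  kind: mvnormal
  mean: [-0.5, -0.25, 0.0, 0.25, 0.5]
  variances: [0.5, 0.5, 0.5, 0.5, 0.5]
membership:
  kind: multinomial
  terms: ["1", "L1", "L2", "L3", "L4", "L5", "L1:L2"]
  coefficients:
    - [0.25, 1.00, 0.55, -0.25, 0.75, -0.25, -0.5]
    - [0.25, 0.35, 0.45, -0.35, 0.65, 0.25, 0.5]
    - [0.25, 1.00, 0.35, -0.45, 0.55, 0.25, 0.5]
    - [0.25, 0.55, 0.25, -0.55, 0.45, -0.25, -0.5]
treatment_rate: 0.5
outcome:
  terms: ["1", "X", "L1", "L2", "L3", "L4", "L5", "X:L1"]
  coefficients: [-0.25, 0.0, 0.5, -0.25, -0.5, 0.25, -0.5, -1.5]
  per_trial:
    X: [-0.25, 0.65, 0.0, 0.5, 0.25]
truth:
  printed_diagonal_rr: [1.55, 1.58, 1.60, 1.57, 1.52]
  unverified_cells: []
  verified: true
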