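# Benchmark setting 3: case-mix heterogeneity with near positivity
# violations.  L1 has a much larger variance (7.5) and the membership model
# includes an L1^2 term, so subjects with extreme L1 are almost never
# recruited into trials 1-2; IPW transport from trial 1 toward trials 3-5
# then hinges on a handful of enormous weights.
# The source table prints no usable diagonal truths for this setting (its
# truth row duplicates the previous setting's); the transcription was
# instead validated against the benchmark's reported population-specific
# pooled log relative risks (-0.74, -0.59, -0.16, -0.19, -0.21), which our
# Monte-Carlo oracle reproduces (0.477, 0.554, 0.859, 0.825, 0.799 on the
# ratio scale).  Those oracle values are therefore stored as reference
# values rather than printed truths.
name: setting3
n_total: 3750
n_trials: 5
covariates: [L1, L2, L3, L4, L5]
covariate_law:
  kind: mvnormal
  mean: [0.5, -0.25, 0.0, 0.25, 0.5]
  variances: [7.5, 2.0, 2.0, 2.0, 2.0]
membership:
  kind: multinomial
  terms: ["1", "L1", "L2", "L3", "L4", "L5", "L1^2"]
  coefficients:
    - [-0.14, -1.16, 0.20, -0.20, 0.20, -0.20, 1.18]
    - [-1.60, -2.02, 0.20, -0.40, 0.40, 0.30, 2.04]
    - [-1.46, -2.00, 0.30, -0.30, 0.30, 0.20, 2.03]
    - [-1.33, -2.00, 0.20, -0.20, 0.40, -0.30, 2.02]
treatment_rate: 0.5
outcome:
  terms: ["1", "X", "L1", "L2", "L3", "L4", "L5", "X:L1"]
  coefficients: [-0.25, -0.5, 0.5, -0.25, -0.5, 0.25, -0.5, -2.0]
truth:
  printed_diagonal_rr: null
  reference_diagonal_rr: [0.477, 0.554, 0.859, 0.825, 0.799]
  unverified_cells: []
  verified: true
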