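# Benchmark setting 4: beyond-case-mix heterogeneity only.  All five trials
# share one multivariate-normal case mix (membership is uniform), but the
# treatment main effect beta_1k differs by trial (the source table's
# trial-indicator labels for the 4th and 5th terms are obvious typos,
# corrected to S=4 and S=5; confirmed by the truth check).  Because all
# transported estimates standardize over the same case mix, log RR(j, k)
# with the same k are almost perfectly correlated and the case-mix Wald
# test covariance M Sigma M' becomes nearly singular here.
name: setting4
n_total: 3750
n_trials: 5
covariates: [L1, L2, L3, L4, L5]
covariate_law:
  kind: mvnormal
  mean: [-0.5, -0.25, 0.0, 0.25, 0.5]
  variances: [0.5, 0.5, 0.5, 0.5, 0.5]
membership:
  kind: uniform
treatment_rate: 0.5
outcome:
  terms: ["1", "X", "L1", "L2", "L3", "L4", "L5", "X:L1"]
  coefficients: [-0.25, 0.0, 0.5, -0.25, -0.5, 0.25, -0.5, -1.5]
  per_trial:
    X: [0.25, 0.05, -0.15, -0.35, -0.50]
truth:
  printed_diagonal_rr: [1.60, 1.49, 1.37, 1.25, 1.16]
  unverified_cells: []
  verified: true
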