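# Benchmark setting 1: case-mix heterogeneity only.
# Five trials drawing the same five Gaussian covariates; trial membership
# depends on the covariates (multinomial logit with an L1*L2 product term);
# one shared logistic outcome model with an X*L1 interaction.  Population
# relative risks differ across trials purely because the case mixes differ.
# Transcribed from a published simulation benchmark whose source table is
# typographically corrupted; this parameterization reproduces all five of
# the benchmark's reported diagonal relative risks (Monte-Carlo check).
name: setting1
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
    - [0.01, 0.45, 0.30, 0.30, 0.30, 0.01, 0.01]
    - [0.01, -0.20, 0.20, 0.20, 0.20, 0.50, -2.25]
    - [0.01, 0.45, 0.10, 0.10, 0.10, 0.50, -2.25]
    - [-0.25, -0.55, -0.25, 0.55, -0.45, 0.25, -1.50]
treatment_rate: 0.5
outcome:
  terms: ["1", "X", "L1", "L2", "L3", "L4", "L5", "X:L1"]
  coefficients: [-0.25, -0.5, 0.5, -0.25, -0.5, 0.25, -0.5, -1.5]
truth:
  printed_diagonal_rr: [1.30, 1.08, 1.20, 0.91, 1.32]
  unverified_cells: []
  verified: true
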