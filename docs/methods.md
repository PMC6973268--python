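# Methods

## Estimands and identification

For K randomized trials with binary treatment X, binary outcome Y, trial
indicator S and baseline covariates L, the estimand grid is
`P{Y(x_k)=1 | S=j}` — the risk population j would experience under trial
k's version of arm x — and the derived effect measures RR(j,k), OR(j,k),
RD(j,k).  Identification requires (i) ignorable study assignment
(Y(x_k) ⊥ S | L: covariates capture everything prognostic that differs
between enrolled populations), (ii) positivity of trial membership
(P(S=j|L) > 0 wherever trial k enrolls), (iii) consistency, and
(iv) within-trial randomization.  None of (i)–(ii) is testable in
general; the package therefore treats extreme membership weights as a
first-class diagnostic rather than a numerical nuisance.

## Estimators

**Outcome regression (OCR).** A maximum-likelihood logistic model with
user-chosen main terms, treatment-covariate interactions and free-form
extra terms is fitted per source trial k (statsmodels GLM, IRLS to
tolerance 1e-10), and its predictions at X=x are averaged over the target
trial j's covariate rows.  Risks are automatically in [0,1]; the failure
mode is silent extrapolation when case mixes barely overlap.

**IPW.** The covariate density ratio w(L) = P(S=j|L)/P(S=k|L) is the
exponential of the linear predictor of a pairwise logistic membership
model (or a ratio of multinomial predicted probabilities).  The
identification formula requires this ratio, not a probability: weights
are unbounded by construction.  The default estimator is the Hájek
(stabilized) ratio Σ Y·1(X=x)·w / Σ 1(X=x)·w over trial k, which is
invariant to rescaling w and cannot leave [0,1].  The unstabilized
estimator divides by the observed arm rate (the randomization-ratio
quantity R_k in disguise) times the target sample size; it is retained,
never clipped, and flags estimates above 1, because that boundary
violation is the diagnostic signature of positivity failure.

Self-transports (j = k) run through the same machinery with unit weights,
so the diagonal of the effect matrix is each trial's own marginal effect.

Degenerate cells (an arm with zero events) raise by default; an explicit
`continuity=True` flag adds half an average-weight pseudo-event and
pseudo-non-event to the Hájek numerator/denominator instead.  No silent
corrections anywhere.

**Weight truncation.** Off by default (the simulation benchmarks do not
truncate).  When enabled (application profile), weights above the
empirical q-quantile (default 0.95, linear interpolation, strictly-above
values reset) are set to that quantile, and any post-truncation weight
above 200 raises the positivity flag.  Truncation is incompatible with
the analytic sandwich (non-smooth estimating equation); use the bootstrap
there.

## Variance estimation

Two routes, agreeing within bootstrap noise (tested):

* **Within-study bootstrap** (default for data analysis): subjects are
  resampled with replacement within each study — trial sizes are design
  constants, so only within-trial sampling variability is targeted — and
  every outcome/PS model is refitted per replicate.  The empirical
  covariance of the stacked K² log effects captures all cross-cell
  correlation.  Replicates that fail (separation, empty cells) are
  dropped and tallied; above 10% failures the estimate aborts.  B and a
  seed are mandatory; B=1000 by default.
* **Sandwich (M-estimation)**: the per-trial logistic scores (outcome
  models for OCR, pairwise membership models for IPW) and the
  standardization functionals for every cell are stacked into one
  estimating-equation system; bread and meat are assembled analytically
  and a delta step maps (p1, p0) to the log effect.  This yields the
  same joint K²×K² covariance at a fraction of the cost and is what the
  replicated benchmarks use.  It is implemented for OCR and for
  stabilized IPW with pairwise PS models; the multinomial-PS joint
  covariance is deliberately left to the bootstrap.

The stacking order is target-major: cell (j,k) sits at index
`j_index*K + k_index`, studies in first-appearance order.

## Pooling and heterogeneity decomposition

For fixed target j the K transported log effects are pooled with a
DerSimonian–Laird random-effects model (τ² truncated at zero; REML
available behind a flag), weights w = 1/(σ̂_jk² + τ̂_j²), Wald CIs on the
log scale.  Because all K estimates describe one case mix, τ̂_j² and the
accompanying I² measure beyond-case-mix heterogeneity only.  The
conventional meta-analysis of the diagonal is computed the same way for
comparison.  Correlation between transported estimates sharing data is
ignored at the pooling stage — that is the two-stage model's own
definition, and the joint covariance is reserved for the tests; the
pooled SEs are therefore approximate (documented caveat).

The Wald tests use (K−1)×K² successive-difference contrasts on the
stacked vector: fixed row j (beyond case mix) or fixed column k (case
mix), T = (Mr)'(MΣM')⁻¹(Mr) against χ²_{K−1}.  The statistic is invariant
to the choice of contrast basis spanning the same null (tested).  When
all trials share one case mix the within-column estimates are almost
perfectly correlated and MΣM' is near-singular; the test then switches to
the Moore–Penrose pseudo-inverse with df = rank and reports a rank
warning instead of failing — this shrinkage makes the case-mix tests
conservative in exactly that scenario, which the shared-case-mix
benchmark setting reproduces.  No multiplicity adjustment by default; a
Bonferroni column is available.

## Simulator and truth oracles

Each shipped setting draws L (multivariate normal with diagonal
covariance, or one uniform law per trial), assigns S by a
multinomial-logit membership model on covariate terms (trial 1 =
reference), uniformly, or in fixed equal blocks; randomizes X ~
Bernoulli(0.5) (1:1, the benchmark's design); and draws Y from a logistic
model whose treatment coefficients may vary by trial.  Defaults: K=5
trials, 3750 subjects total; setting 5 uses fixed sizes of 750 because it
specifies per-trial covariate laws rather than a membership model.

Truth oracles: where the trial-conditional covariate law is closed form
the standardized risks are computed by deterministic quadrature —
Gauss–Legendre over each per-trial uniform, or, for a common Gaussian
case mix with an outcome model nonlinear only in L1, a two-dimensional
Gauss–Hermite rule over (L1, the Gaussian aggregate of the remaining
linear terms) — with 80 nodes, far below 1e-6 absolute error.  Where
membership depends on covariates the oracle is Monte Carlo (default
5×10⁶ draws) with delta-method MC standard errors reported per cell.
Quadrature and MC agree within 3 MC-SE (tested).

The five shipped YAML settings are transcriptions of a published
benchmark whose source table is typographically corrupted.  Each
transcription is validated against the values the benchmark prints:
settings 1, 2 and 4 reproduce every printed diagonal RR to 2 d.p.; two
obvious trial-indicator typos in the per-trial treatment coefficients of
settings 2 and 4 were corrected (and confirmed by that validation).  Two
printed cells of setting 5 (0.82, 0.79) are inconsistent with both the
exact quadrature (0.832, 0.831) and the benchmark's own pooled summaries
(exp(−0.18) ≈ 0.84); they are flagged `unverified_cells` in the config
and skipped by `check_printed_truths`.  Setting 3's printed truth row
duplicates setting 2's, so its config instead stores oracle reference
values validated against the benchmark's pooled summaries.  A
transcription that failed validation would ship flagged unverified, not
silently.

## Benchmark runner and problem sizes

`run_benchmark` generates replicate datasets, runs the full pipeline
(effect matrix, joint sandwich covariance, population-specific and
conventional pooling, both Wald-test families) and aggregates bias,
τ²/I² distributions and rejection rates.  The package's chosen problem
sizes: 500 replicates of 3750 subjects for the calibration checks
(type-I error band = 3-sigma binomial around 5%), 30 replicates for the
directional misspecification/positivity checks, 5×10⁶ draws for MC
truths.  These reduced-scale runs reproduce the benchmark's qualitative
structure; full-scale replication (thousands of replicates) is a
config choice, not a code change.

What passing simulations do not show: the generator draws complete,
perfectly measured covariates, honest 1:1 randomization and correctly
typed binary outcomes, so the tests say nothing about missing data,
measurement error, clustering (cluster-randomized designs are out of
scope) or model selection on real data.

## Numerical choices

* Logistic fits: statsmodels GLM/Binomial, IRLS, tol 1e-10, maxiter 200.
  Perfect separation raises a convergence error naming the context (for
  membership models it is reported as a deterministic positivity
  violation).  Extreme but converged fits are *not* errors: they are the
  expected signature of weak overlap and surface via the weight
  diagnostics.  PS linear predictors are clipped at ±500 before
  exponentiation to avoid overflow; at that point the weight is already
  purely diagnostic.
* Covariances are validated symmetric and PSD to 1e-8 before use.
* MΣM' is inverted directly below condition number 1e12, by
  pseudo-inverse (rcond 1e-10) with df = rank above it.
* DL τ² truncates at 0; REML uses bounded scalar minimization with an
  explicit boundary comparison at τ² = 0.
* All simulation randomness flows from `numpy.random.default_rng` /
  `SeedSequence.spawn`; every stochastic entry point takes a seed and
  refuses to run without one where reproducibility matters (bootstrap,
  CLI simulation).

## Known limitations

* Pooled SEs ignore cross-cell correlation (two-stage convention).
* The analytic sandwich does not cover the unstabilized IPW estimator,
  multinomial PS models, or truncated weights (bootstrap does).
* Binary outcomes only; no survival/continuous outcomes, no
  doubly-robust estimators, no systematically missing covariates,
  no aggregate-data mode.
* The case-mix Wald test is conservative under a shared case mix (see
  above); more sophisticated covariance estimation would be needed there.
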