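"""Replicated simulation benchmark: bias, heterogeneity, test calibration.

For a simulation setting and one or more estimator configurations this
module repeatedly generates data, estimates the full transported-effect
matrix with its joint covariance, runs the population-specific and
conventional meta-analyses and both Wald test families, and aggregates:

* absolute and relative bias of the transported risks P{Y(1_k)=1|S=j} and
  of RR(j, k) against the setting's truth oracle;
* the distribution (mean/median) of the pooled log effects, between-trial
  variances tau_j^2 and I^2, for each target population and for the
  conventional diagonal meta-analysis;
* rejection rates at level alpha of the beyond-case-mix and case-mix Wald
  tests and of the conventional Cochran Q test.

The joint covariance uses the analytic sandwich (stacked estimating
equations) for speed; IPW runs use pairwise-logistic PS models, which are
correctly specified whenever the generative membership model is a
multinomial logit on the same terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError
from .heterogeneity import KINDS, wald_test
from .pooling import conventional_meta, pool_population
from .simulate import SimSetting, TruthTable, generate, true_values
from .standardize import OutcomeModelSpec, PSModelSpec, estimate_effect_matrix
from .variance import sandwich_covariance

__all__ = ["EstimatorConfig", "BenchmarkResult", "default_estimators", "run_benchmark"]


@dataclass(frozen=True)
class EstimatorConfig:
    """One estimator arm of the benchmark (e.g. correctly specified OCR)."""

    name: str
    method: str  # 'OCR' | 'IPW'
    outcome_spec: OutcomeModelSpec | None = None
    ps_spec: PSModelSpec | None = None
    measure: str = "RR"


def _patsy_terms(terms) -> list:
    """Simulator term syntax ('L1^2', 'L1:L2') -> patsy ('I(L1**2)', 'L1:L2')."""
    out = []
    for t in terms:
        if "^" in t:
            name, power = t.split("^")
            out.append(f"I({name}**{int(power)})")
        else:
            out.append(t)
    return out


def default_estimators(setting: SimSetting, misspecified: bool = False) -> list:
    """Correctly specified OCR and IPW configurations for a setting, or the
    deliberately misspecified variants (OCRw drops the treatment-covariate
    interaction; IPWw drops the covariate-covariate interaction term)."""
    out_terms = list(setting.outcome["terms"])
    mains = [t for t in out_terms if ":" not in t and t not in ("1", "X")]
    inters = [t.split(":")[1] for t in out_terms if t.startswith("X:")]
    if misspecified:
        inters = []
    outcome = OutcomeModelSpec(
        main_terms=tuple(_patsy_terms([t for t in mains if "^" not in t])),
        treatment_interactions=tuple(inters),
        extra_terms=tuple(_patsy_terms([t for t in mains if "^" in t])),
    )
    if setting.membership["kind"] == "multinomial":
        ps_terms = [t for t in setting.membership["terms"] if t != "1"]
        if misspecified:
            ps_terms = [t for t in ps_terms if ":" not in t and "^" not in t]
    else:
        ps_terms = list(setting.covariates)
    ps = PSModelSpec(terms=tuple(_patsy_terms(ps_terms)), mode="pairwise")
    suffix = "w" if misspecified else ""
    return [
        EstimatorConfig(f"OCR{suffix}", "OCR", outcome_spec=outcome),
        EstimatorConfig(f"IPW{suffix}", "IPW", ps_spec=ps),
    ]


@dataclass
class BenchmarkResult:
    setting: str
    replicates: int
    alpha: float
    truth: TruthTable
    risk_bias: pd.DataFrame  # per (estimator, target_j, source_k), x=1 scale
    rr_bias: pd.DataFrame
    pooling: pd.DataFrame  # per (estimator, target_j)
    conventional: pd.DataFrame  # per estimator
    rejection: pd.DataFrame  # per (estimator, kind, fixed)
    diagnostics: pd.DataFrame  # positivity flags / boundary violations per cell
    n_failed: dict = field(default_factory=dict)


def run_benchmark(
    setting: SimSetting,
    estimators=None,
    replicates: int = 200,
    seed: int = 0,
    truth: TruthTable | None = None,
    alpha: float = 0.05,
    n_total: int | None = None,
    truth_mc_draws: int = 5_000_000,
) -> BenchmarkResult:
    """Run the full reduced-scale benchmark for one setting.

    Replicates where any estimator arm fails outright (separation, empty
    cells) are dropped for that arm and tallied in ``n_failed``.
    """
    if estimators is None:
        estimators = default_estimators(setting)
    # seeds: one stream for truth, one per replicate
    root = np.random.SeedSequence(seed)
    truth_seed, *rep_seeds = root.spawn(replicates + 1)
    if truth is None:
        truth = true_values(
            setting, "auto", mc_draws=truth_mc_draws,
            seed=np.random.default_rng(truth_seed),
        )
    studies = setting.studies
    K = len(studies)
    acc = {
        cfg.name: {
            "risk1": [], "rr": [], "log_pooled": [], "tau2": [], "i2": [],
            "conv": [], "reject": [], "positivity": [], "failed": 0,
        }
        for cfg in estimators
    }
    for r in range(replicates):
        rng = np.random.default_rng(rep_seeds[r])
        table = generate(setting, rng, n_total=n_total)
        for cfg in estimators:
            a = acc[cfg.name]
            try:
                matrix = estimate_effect_matrix(
                    table, cfg.method, cfg.outcome_spec, cfg.ps_spec, cfg.measure
                )
                if matrix.errors:
                    raise EstimationError(
                        f"cells failed: {sorted(matrix.errors)[:3]}"
                    )
                cov = sandwich_covariance(
                    table, cfg.method, cfg.outcome_spec, cfg.ps_spec, cfg.measure
                )
                matrix.set_covariance(cov.sigma, "sandwich")
            except EstimationError:
                a["failed"] += 1
                continue
            a["risk1"].append(
                [[matrix.cell(j, k).diagnostics["p1"] for k in studies] for j in studies]
            )
            a["rr"].append([[matrix.cell(j, k).point for k in studies] for j in studies])
            a["positivity"].append(
                [[bool(matrix.cell(j, k).diagnostics.get("positivity_flag", False))
                  for k in studies] for j in studies]
            )
            pooled = [pool_population(matrix.row(j)) for j in studies]
            a["log_pooled"].append([p.log_pooled for p in pooled])
            a["tau2"].append([p.tau2 for p in pooled])
            a["i2"].append([p.i2 for p in pooled])
            conv = conventional_meta(matrix)
            a["conv"].append(
                [conv.log_pooled, conv.tau2, conv.i2, conv.q_pvalue < alpha]
            )
            rej = []
            for kind in KINDS:
                for s in studies:
                    t = wald_test(matrix, s, kind)
                    rej.append(t.p_value < alpha)
            a["reject"].append(rej)

    risk_rows, rr_rows, pool_rows, conv_rows, rej_rows, diag_rows = [], [], [], [], [], []
    for cfg in estimators:
        a = acc[cfg.name]
        if not a["risk1"]:
            continue
        risk1 = np.asarray(a["risk1"])  # R x K x K
        rr = np.asarray(a["rr"])
        pos = np.asarray(a["positivity"], float)
        for ji, j in enumerate(studies):
            for ki, k in enumerate(studies):
                t_risk = truth.risk(j, k, 1)
                t_rr = truth.rr[(j, k)]
                mean_risk = risk1[:, ji, ki].mean()
                mean_rr = rr[:, ji, ki].mean()
                risk_rows.append(
                    {"estimator": cfg.name, "target_j": j, "source_k": k,
                     "mean": mean_risk, "truth": t_risk,
                     "bias": mean_risk - t_risk,
                     "rel_bias_pct": 100 * (mean_risk - t_risk) / t_risk}
                )
                rr_rows.append(
                    {"estimator": cfg.name, "target_j": j, "source_k": k,
                     "mean": mean_rr, "truth": t_rr, "bias": mean_rr - t_rr,
                     "rel_bias_pct": 100 * (mean_rr - t_rr) / t_rr}
                )
                diag_rows.append(
                    {"estimator": cfg.name, "target_j": j, "source_k": k,
                     "positivity_rate": pos[:, ji, ki].mean()}
                )
        lp = np.asarray(a["log_pooled"])
        tau2 = np.asarray(a["tau2"])
        i2 = np.asarray(a["i2"])
        for ji, j in enumerate(studies):
            pool_rows.append(
                {"estimator": cfg.name, "target_j": j,
                 "mean_log_pooled": lp[:, ji].mean(),
                 "median_tau2": float(np.median(tau2[:, ji])),
                 "median_i2": float(np.median(i2[:, ji]))}
            )
        conv = np.asarray(a["conv"])
        conv_rows.append(
            {"estimator": cfg.name, "mean_log_pooled": conv[:, 0].mean(),
             "median_tau2": float(np.median(conv[:, 1])),
             "median_i2": float(np.median(conv[:, 2])),
             "q_rejection_rate": conv[:, 3].mean()}
        )
        rej = np.asarray(a["reject"], float)
        col = 0
        for kind in KINDS:
            for s in studies:
                rej_rows.append(
                    {"estimator": cfg.name, "kind": kind, "fixed": s,
                     "rejection_rate": rej[:, col].mean()}
                )
                col += 1
    return BenchmarkResult(
        setting=setting.name,
        replicates=replicates,
        alpha=alpha,
        truth=truth,
        risk_bias=pd.DataFrame(risk_rows),
        rr_bias=pd.DataFrame(rr_rows),
        pooling=pd.DataFrame(pool_rows),
        conventional=pd.DataFrame(conv_rows),
        rejection=pd.DataFrame(rej_rows),
        diagnostics=pd.DataFrame(diag_rows),
        n_failed={cfg.name: acc[cfg.name]["failed"] for cfg in estimators},
    )
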