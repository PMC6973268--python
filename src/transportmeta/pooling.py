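"""Two-stage random-effects pooling of transported effects.

For a fixed target population j the K transported log effects
log RR(j, 1..K) share one case mix, so their random-effects summary
log RR(j.) and between-trial variance tau_j^2 describe *beyond* case-mix
heterogeneity only.  The conventional meta-analysis of the diagonal
log RR(j, j) — each trial analysed in its own population — is provided for
comparison; its heterogeneity mixes both sources.

tau^2 is estimated by DerSimonian-Laird (truncated at zero) by default,
with REML behind a flag; weights are inverse total variances
w = 1/(sigma_jk^2 + tau^2) and confidence intervals are normal (Wald) on
the log scale.  Correlation between transported estimates that share data
is deliberately ignored at this stage, exactly as the two-stage model
specifies; the joint covariance is used only by the Wald heterogeneity
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EstimationError
from .standardize import EffectMatrix, TransportEstimate

__all__ = [
    "PooledResult",
    "dersimonian_laird",
    "pool_population",
    "pool_all_populations",
    "conventional_meta",
]


@dataclass
class PooledResult:
    """Random-effects summary for one target population (or 'conventional')."""

    target_j: object
    measure: str
    log_pooled: float
    se_pooled: float
    tau2: float
    i2: float  # percent, in [0, 100]
    q: float
    q_df: int
    q_pvalue: float
    per_study_weights: np.ndarray
    sources: list
    per_study_effects: np.ndarray | None = None
    per_study_se: np.ndarray | None = None
    method: str = "DL"

    @property
    def point(self) -> float:
        return float(np.exp(self.log_pooled)) if self.measure in ("RR", "OR") else self.log_pooled

    @property
    def ci95(self) -> tuple[float, float]:
        lo = self.log_pooled - 1.959963984540054 * self.se_pooled
        hi = self.log_pooled + 1.959963984540054 * self.se_pooled
        if self.measure in ("RR", "OR"):
            return float(np.exp(lo)), float(np.exp(hi))
        return float(lo), float(hi)

    def to_frame(self) -> pd.DataFrame:
        """Forest-plot-ready long frame: one row per source plus a pooled row."""
        eff = self.per_study_effects
        ses = self.per_study_se
        rows = [
            {"study": s, "weight": w,
             "log_effect": None if eff is None else eff[i],
             "se": None if ses is None else ses[i]}
            for i, (s, w) in enumerate(zip(self.sources, self.per_study_weights))
        ]
        rows.append(
            {"study": "pooled", "log_effect": self.log_pooled, "se": self.se_pooled,
             "tau2": self.tau2, "i2": self.i2, "q": self.q, "weight": np.nan}
        )
        return pd.DataFrame(rows)


def dersimonian_laird(y: np.ndarray, v: np.ndarray) -> float:
    """Method-of-moments between-trial variance, truncated at zero."""
    w = 1.0 / v
    mu_fe = (w * y).sum() / w.sum()
    q = float((w * (y - mu_fe) ** 2).sum())
    df = len(y) - 1
    denom = w.sum() - (w ** 2).sum() / w.sum()
    return max(0.0, (q - df) / denom)


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    def neg_restricted_ll(tau2):
        wt = 1.0 / (v + tau2)
        mu = (wt * y).sum() / wt.sum()
        return 0.5 * (
            np.log(v + tau2).sum() + np.log(wt.sum()) + (wt * (y - mu) ** 2).sum()
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, 10.0 * max(v.max(), y.var() + 1e-12)),
        method="bounded",
    )
    # the bounded optimizer cannot sit exactly on the boundary
    if neg_restricted_ll(0.0) <= res.fun:
        return 0.0
    return float(max(0.0, res.x))


def _pool(y, v, target, measure, sources, method):
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if len(y) < 2:
        raise EstimationError(
            f"need at least 2 usable estimates to pool (target {target!r}, got {len(y)})"
        )
    if np.any(v <= 0) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(v)):
        raise EstimationError(f"non-finite effects or variances for target {target!r}")
    w_fe = 1.0 / v
    mu_fe = (w_fe * y).sum() / w_fe.sum()
    q = float((w_fe * (y - mu_fe) ** 2).sum())
    df = len(y) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    tau2 = _reml_tau2(y, v) if method == "REML" else dersimonian_laird(y, v)
    w = 1.0 / (v + tau2)
    mu = float((w * y).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return PooledResult(
        target_j=target,
        measure=measure,
        log_pooled=mu,
        se_pooled=se,
        tau2=float(tau2),
        i2=float(i2),
        q=q,
        q_df=df,
        q_pvalue=float(stats.chi2.sf(q, df)),
        per_study_weights=w,
        sources=list(sources),
        per_study_effects=y,
        per_study_se=np.sqrt(v),
        method=method,
    )


def pool_population(
    estimates,
    variances=None,
    target=None,
    measure: str | None = None,
    method: str = "DL",
) -> PooledResult:
    """Pool the K transported effects sharing one target population j.

    ``estimates`` is either a list of :class:`TransportEstimate` (with
    ``se`` filled, or ``variances`` given separately) or a plain array of
    log effects with ``variances``.
    """
    if len(estimates) and isinstance(estimates[0], TransportEstimate):
        ests = list(estimates)
        targets = {e.target_j for e in ests}
        if len(targets) != 1:
            raise ValueError(f"estimates mix target populations: {targets}")
        target = ests[0].target_j if target is None else target
        measure = ests[0].measure if measure is None else measure
        y = [e.log_point for e in ests]
        if variances is None:
            if any(e.se is None for e in ests):
                raise EstimationError("estimates carry no SEs and no variances given")
            variances = [e.se ** 2 for e in ests]
        sources = [e.source_k for e in ests]
    else:
        y = estimates
        if variances is None:
            raise ValueError("variances required with raw effect arrays")
        sources = list(range(1, len(y) + 1))
        measure = measure or "RR"
    return _pool(y, variances, target, measure, sources, method)


def pool_all_populations(matrix: EffectMatrix, method: str = "DL") -> dict:
    """One population-specific pooled summary per target j (label -> result)."""
    out = {}
    for j in matrix.studies:
        out[j] = pool_population(matrix.row(j), method=method)
    return out


def conventional_meta(matrix: EffectMatrix, method: str = "DL") -> PooledResult:
    """Standard two-step meta-analysis of the diagonal (each trial analysed
    in its own population), without case-mix standardization across trials."""
    diag = matrix.diagonal()
    if len(diag) < 2:
        raise EstimationError(
            f"conventional meta-analysis needs >=2 diagonal estimates, got {len(diag)}"
        )
    if any(e.se is None for e in diag):
        raise EstimationError("diagonal estimates carry no standard errors")
    y = [e.log_point for e in diag]
    v = [e.se ** 2 for e in diag]
    return _pool(y, v, "conventional", matrix.measure, [e.source_k for e in diag], method)
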