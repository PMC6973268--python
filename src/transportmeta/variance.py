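"""Standard errors and joint covariance of the stacked transported log effects.

Two routes are provided:

* **bootstrap** — nonparametric resampling of subjects with replacement
  within each study (trials are fixed by design), refitting every outcome
  and PS model per replicate; the empirical covariance of the stacked
  K^2 log effects captures the cross-cell correlation induced by shared
  data, which the Wald heterogeneity tests need.
* **sandwich** — M-estimation: the per-trial model scores and the
  standardization functionals are stacked into one estimating-equation
  system; the bread/meat sandwich with a delta step for the log transform
  yields the same joint covariance analytically.  Implemented for OCR and
  for stabilized IPW with pairwise-logistic PS models (the multinomial-PS
  joint covariance is served by the bootstrap).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import patsy
from scipy.special import expit

from .errors import EstimationError
from .ipd import IPDTable, OUTCOME, TREATMENT
from .standardize import (
    OutcomeModelSpec,
    PSModelSpec,
    _fit_logit,
    estimate_effect_matrix,
)

__all__ = [
    "CovarianceEstimate",
    "bootstrap_covariance",
    "sandwich_covariance",
    "sandwich_se",
    "pipeline_estimator",
]


@dataclass
class CovarianceEstimate:
    """Joint covariance of the stacked log effects (target-major order)."""

    sigma: np.ndarray
    method: str  # 'bootstrap' | 'sandwich'
    studies: list
    B: int | None = None
    seed: int | None = None
    n_failed: int = 0

    def labels(self) -> list:
        return [f"{j}:{k}" for j in self.studies for k in self.studies]

    def to_frame(self) -> pd.DataFrame:
        lab = self.labels()
        return pd.DataFrame(self.sigma, index=lab, columns=lab)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def pipeline_estimator(
    method: str = "OCR",
    outcome_spec: OutcomeModelSpec | None = None,
    ps_spec: PSModelSpec | None = None,
    measure: str = "RR",
    **options,
) -> Callable[[IPDTable], np.ndarray]:
    """A configured end-to-end estimator: table -> stacked log effects."""

    def run(table: IPDTable) -> np.ndarray:
        m = estimate_effect_matrix(
            table, method, outcome_spec, ps_spec, measure, **options
        )
        return m.stacked()

    return run


def bootstrap_covariance(
    table: IPDTable,
    estimator: Callable[[IPDTable], np.ndarray],
    B: int = 1000,
    seed: int | None = None,
    max_failure_rate: float = 0.10,
) -> CovarianceEstimate:
    """Within-study bootstrap covariance of the stacked estimator.

    Replicates in which any model fails (separation, empty cells — any
    non-finite entry in the stacked vector or a raised estimation error)
    are dropped and counted; more than ``max_failure_rate`` failures raise.
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap replicates")
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    draws, n_failed = [], 0
    for _ in range(B):
        resampled = table.resample_within_studies(rng)
        try:
            vec = np.asarray(estimator(resampled), float)
        except EstimationError:
            n_failed += 1
            continue
        if not np.all(np.isfinite(vec)):
            n_failed += 1
            continue
        draws.append(vec)
    if n_failed > max_failure_rate * B:
        raise EstimationError(
            f"bootstrap unstable: {n_failed}/{B} replicates failed "
            "(separation or empty cells in resamples)"
        )
    arr = np.asarray(draws)
    sigma = np.atleast_2d(np.cov(arr, rowvar=False, ddof=1))
    return CovarianceEstimate(
        sigma, "bootstrap", list(table.studies), B=B, seed=seed, n_failed=n_failed
    )


# ---------------------------------------------------------------------------
# sandwich (stacked estimating equations)
# ---------------------------------------------------------------------------


def _loggrad(measure: str, p1: float, p0: float) -> tuple[float, float]:
    """d(log effect)/d(p1, p0) for the delta step."""
    if measure == "RR":
        return 1.0 / p1, -1.0 / p0
    if measure == "OR":
        return 1.0 / (p1 * (1.0 - p1)), -1.0 / (p0 * (1.0 - p0))
    return 1.0, -1.0  # RD on its raw scale


def _sandwich_ocr(table, cells, outcome_spec, measure):
    df = table.data
    y = df[OUTCOME].to_numpy(float)
    dm = patsy.dmatrix(outcome_spec.rhs(), df)
    D_obs = np.asarray(dm)
    D_x = {
        x: np.asarray(
            patsy.build_design_matrices([dm.design_info], df.assign(**{TREATMENT: x}))[0]
        )
        for x in (0, 1)
    }
    n, p = D_obs.shape
    masks = {s: table.mask(s) for s in table.studies}

    sources = sorted({k for _, k in cells}, key=table.studies.index)
    beta = {}
    for k in sources:
        mk = masks[k]
        beta[k] = _fit_logit(y[mk], D_obs[mk], f"outcome model of trial {k!r}")

    k_off = {k: i * p for i, k in enumerate(sources)}
    n_beta = len(sources) * p
    P = n_beta + 2 * len(cells)
    psi = np.zeros((n, P))
    A = np.zeros((P, P))

    for k in sources:
        mk = masks[k]
        mu = expit(D_obs[mk] @ beta[k])
        sl = slice(k_off[k], k_off[k] + p)
        psi[mk, sl] = (y[mk] - mu)[:, None] * D_obs[mk]
        A[sl, sl] = (D_obs[mk] * (mu * (1 - mu))[:, None]).T @ D_obs[mk] / n

    grads = np.zeros((len(cells), P))
    for c, (j, k) in enumerate(cells):
        mj = masks[j]
        nj = mj.sum()
        pvals = {}
        for x in (0, 1):
            col = n_beta + 2 * c + x  # x=0 first, x=1 second
            mu_x = expit(D_x[x][mj] @ beta[k])
            pvals[x] = mu_x.mean()
            psi[mj, col] = mu_x - pvals[x]
            A[col, col] = nj / n
            sl = slice(k_off[k], k_off[k] + p)
            A[col, sl] = -(D_x[x][mj] * (mu_x * (1 - mu_x))[:, None]).sum(axis=0) / n
        g1, g0 = _loggrad(measure, pvals[1], pvals[0])
        grads[c, n_beta + 2 * c + 1] = g1
        grads[c, n_beta + 2 * c + 0] = g0
    return psi, A, grads


def _sandwich_ipw(table, cells, ps_spec, measure):
    if ps_spec.mode != "pairwise":
        raise EstimationError(
            "analytic sandwich covariance is implemented for pairwise PS "
            "models only; use bootstrap_covariance with multinomial PS"
        )
    df = table.data
    y = df[OUTCOME].to_numpy(float)
    x_obs = df[TREATMENT].to_numpy(int)
    dm = patsy.dmatrix(ps_spec.rhs(), df)
    Z = np.asarray(dm)
    n, q = Z.shape
    masks = {s: table.mask(s) for s in table.studies}
    order = {s: i for i, s in enumerate(table.studies)}

    # unordered pairs, modeled category = the earlier study in label order
    pairs = sorted(
        {tuple(sorted((j, k), key=order.get)) for j, k in cells if j != k},
        key=lambda t: (order[t[0]], order[t[1]]),
    )
    gamma, pair_off = {}, {}
    off = 0
    for a, b in pairs:
        m = masks[a] | masks[b]
        gamma[(a, b)] = _fit_logit(
            masks[a][m].astype(float), Z[m], f"PS model for pair ({a!r},{b!r})"
        )
        pair_off[(a, b)] = off
        off += q
    n_gamma = off
    P = n_gamma + 2 * len(cells)
    psi = np.zeros((n, P))
    A = np.zeros((P, P))

    for a, b in pairs:
        m = masks[a] | masks[b]
        g = gamma[(a, b)]
        mu = expit(Z[m] @ g)
        sl = slice(pair_off[(a, b)], pair_off[(a, b)] + q)
        psi[m, sl] = (masks[a][m].astype(float) - mu)[:, None] * Z[m]
        A[sl, sl] = (Z[m] * (mu * (1 - mu))[:, None]).T @ Z[m] / n

    grads = np.zeros((len(cells), P))
    for c, (j, k) in enumerate(cells):
        mk = masks[k]
        if j == k:
            w = np.ones(mk.sum())
            sign, sl = 0.0, None
        else:
            a, b = sorted((j, k), key=order.get)
            g = gamma[(a, b)]
            sign = 1.0 if a == j else -1.0
            w = np.exp(sign * (Z[mk] @ g))
            sl = slice(pair_off[(a, b)], pair_off[(a, b)] + q)
        pvals = {}
        for x in (0, 1):
            col = n_gamma + 2 * c + x
            arm = x_obs[mk] == x
            w_arm = w[arm]
            if w_arm.sum() == 0:
                raise EstimationError(
                    f"zero total weight in arm X={x} of trial {k!r}"
                )
            pvals[x] = float((y[mk][arm] * w_arm).sum() / w_arm.sum())
            resid = w * (x_obs[mk] == x) * (y[mk] - pvals[x])
            psi[mk, col] = resid
            A[col, col] = w_arm.sum() / n
            if sl is not None:
                A[col, sl] = -sign * (resid[:, None] * Z[mk]).sum(axis=0) / n
        g1, g0 = _loggrad(measure, pvals[1], pvals[0])
        grads[c, n_gamma + 2 * c + 1] = g1
        grads[c, n_gamma + 2 * c + 0] = g0
    return psi, A, grads


def _sandwich(table, cells, method, outcome_spec, ps_spec, measure):
    if method == "OCR":
        if outcome_spec is None:
            raise ValueError("OCR sandwich requires an outcome_spec")
        psi, A, grads = _sandwich_ocr(table, cells, outcome_spec, measure)
    elif method == "IPW":
        if ps_spec is None:
            raise ValueError("IPW sandwich requires a ps_spec")
        psi, A, grads = _sandwich_ipw(table, cells, ps_spec, measure)
    else:
        raise EstimationError(
            f"sandwich covariance not available for method {method!r}; "
            "use bootstrap_covariance"
        )
    n = psi.shape[0]
    B = psi.T @ psi / n
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular bread matrix in sandwich estimator") from exc
    V = Ainv @ B @ Ainv.T / n
    return grads @ V @ grads.T


def sandwich_covariance(
    table: IPDTable,
    method: str = "OCR",
    outcome_spec: OutcomeModelSpec | None = None,
    ps_spec: PSModelSpec | None = None,
    measure: str = "RR",
) -> CovarianceEstimate:
    """Joint K^2 x K^2 sandwich covariance of all transported log effects."""
    cells = [(j, k) for j in table.studies for k in table.studies]
    sigma = _sandwich(table, cells, method, outcome_spec, ps_spec, measure)
    return CovarianceEstimate(sigma, "sandwich", list(table.studies))


def sandwich_se(
    table: IPDTable,
    j,
    k,
    method: str = "OCR",
    outcome_spec: OutcomeModelSpec | None = None,
    ps_spec: PSModelSpec | None = None,
    measure: str = "RR",
) -> float:
    """Sandwich standard error of one transported log effect."""
    sigma = _sandwich(table, [(j, k)], method, outcome_spec, ps_spec, measure)
    return float(np.sqrt(sigma[0, 0]))
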