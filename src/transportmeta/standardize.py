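"""Case-mix standardization of trial treatment effects.

For every ordered pair of trials (j, k) the transported risk
``P{Y(x_k)=1 | S=j}`` — the event probability population j would experience
under trial k's version of arm x — is estimated either by

* outcome regression (OCR, g-computation): fit a logistic outcome model on
  trial k and average its predictions over trial j's covariate records; or
* inverse probability weighting (IPW): reweight trial k's subjects by the
  estimated covariate density ratio w(L) = P(S=j|L)/P(S=k|L), from a
  pairwise logistic or multinomial trial-membership (propensity score)
  model.  The default Hajek (stabilized) form normalizes by the weight sum
  within each arm, which keeps the risk in [0, 1]; the unstabilized form is
  retained to demonstrate boundary violations and is never clipped.

Risks are combined into relative risks, odds ratios or risk differences,
and assembled into the K x K :class:`EffectMatrix` consumed by the pooling
and heterogeneity modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy.special import expit

from .errors import (
    ConvergenceError,
    DegenerateMeasureError,
    DegenerateOutcomeError,
    EstimationError,
    PositivityError,
    SchemaError,
)
from .ipd import IPDTable, OUTCOME, STUDY, TREATMENT

__all__ = [
    "OutcomeModelSpec",
    "PSModelSpec",
    "StandardizedRisk",
    "TransportEstimate",
    "EffectMatrix",
    "WeightSummary",
    "fit_outcome_model",
    "ocr_standardized_risk",
    "fit_ps_model",
    "ipw_standardized_risk",
    "effect_measure",
    "estimate_effect_matrix",
    "truncate_weights",
]

MEASURES = ("RR", "OR", "RD")
METHODS = ("OCR", "IPW", "IPW-unstabilized")

#: default large-weight threshold flagging potential positivity violations
LARGE_WEIGHT_THRESHOLD = 200.0


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Logistic outcome model for one source trial.

    The linear predictor is ``b0 + b1*X + b2'L + b3'(X*L)`` with ``L`` the
    ``main_terms``, ``X*L`` the ``treatment_interactions`` and arbitrary
    patsy terms (e.g. ``"I(L1**2)"``) in ``extra_terms``.
    """

    main_terms: tuple = ()
    treatment_interactions: tuple = ()
    extra_terms: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "main_terms", tuple(self.main_terms))
        object.__setattr__(
            self, "treatment_interactions", tuple(self.treatment_interactions)
        )
        object.__setattr__(self, "extra_terms", tuple(self.extra_terms))

    def rhs(self) -> str:
        parts = [TREATMENT, *self.main_terms, *self.extra_terms]
        parts += [f"{TREATMENT}:{t}" for t in self.treatment_interactions]
        return " + ".join(parts)


@dataclass(frozen=True)
class PSModelSpec:
    """Trial-membership (propensity score) model.

    ``mode='pairwise'`` fits a logistic model of membership-in-j among the
    rows of trials {j, k}; ``mode='multinomial'`` fits one multinomial
    logistic model over all K studies (reference: first study label).
    """

    terms: tuple = ()
    mode: str = "pairwise"

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        if self.mode not in ("pairwise", "multinomial"):
            raise ValueError(f"unknown PS mode {self.mode!r}")

    def rhs(self) -> str:
        return " + ".join(self.terms) if self.terms else "1"


def _check_terms_exist(table: IPDTable, rhs: str, what: str):
    try:
        patsy.dmatrix(rhs, table.data.head(5))
    except (patsy.PatsyError, KeyError) as exc:
        raise SchemaError(f"{what} refers to unknown columns: {exc}") from exc


# ---------------------------------------------------------------------------
# diagnostics containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightSummary:
    """Distributional summary of the IPW weights actually used in one arm."""

    max: float
    p95: float
    ess: float  # Kish effective sample size (sum w)^2 / sum w^2
    n: int
    positivity_flag: bool

    @staticmethod
    def from_weights(w: np.ndarray, threshold: float = LARGE_WEIGHT_THRESHOLD):
        w = np.asarray(w, float)
        ess = float(w.sum() ** 2 / (w ** 2).sum()) if w.size else 0.0
        return WeightSummary(
            max=float(w.max()) if w.size else 0.0,
            p95=float(np.quantile(w, 0.95)) if w.size else 0.0,
            ess=ess,
            n=int(w.size),
            positivity_flag=bool(w.size and w.max() > threshold),
        )


@dataclass(frozen=True)
class TruncationDiagnostics:
    quantile: float
    cutoff: float
    n_truncated: int
    positivity_flag: bool


def truncate_weights(
    weights,
    q: float = 0.95,
    large_weight_threshold: float = LARGE_WEIGHT_THRESHOLD,
):
    """Reset weights above the empirical ``q``-quantile to that quantile.

    The quantile uses linear interpolation; only values strictly greater
    than the cutoff are reset.  Returns ``(truncated, diagnostics)`` where
    the positivity flag reports whether any *post-truncation* weight still
    exceeds ``large_weight_threshold``.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"truncation quantile must be in (0,1), got {q}")
    w = np.asarray(weights, float)
    cutoff = float(np.quantile(w, q))
    out = np.minimum(w, cutoff)
    n_trunc = int((w > cutoff).sum())
    flag = bool(out.size and out.max() > large_weight_threshold)
    return out, TruncationDiagnostics(q, cutoff, n_trunc, flag)


# ---------------------------------------------------------------------------
# outcome regression
# ---------------------------------------------------------------------------


def _fit_logit(y: np.ndarray, X: np.ndarray, context: str):
    """Maximum-likelihood logistic fit with separation detection."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=200, tol=1e-10
            )
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
        ) as exc:
            raise ConvergenceError(f"perfect separation in {context}") from exc
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular design in {context}") from exc
    params = np.asarray(res.params, float)
    # extreme but finite fits are legitimate (they signal poor overlap and
    # surface as large weights); only outright divergence is an error
    if not np.all(np.isfinite(params)) or not getattr(res, "converged", True):
        raise ConvergenceError(
            f"fit diverged in {context} (separation or quasi-separation)"
        )
    return params


class OutcomeModelFit:
    """Fitted per-trial logistic outcome model plus its design builder."""

    def __init__(self, study, spec, params, design_info, param_names):
        self.study = study
        self.spec = spec
        self.params = params
        self.design_info = design_info
        self.param_names = list(param_names)

    def design(self, df: pd.DataFrame, x: int | None = None) -> np.ndarray:
        """Model matrix for ``df``; ``x`` forces the treatment column."""
        if x is not None:
            df = df.assign(**{TREATMENT: x})
        try:
            return np.asarray(
                patsy.build_design_matrices([self.design_info], df)[0]
            )
        except (patsy.PatsyError, KeyError) as exc:
            raise SchemaError(
                f"covariate required by the outcome model is unavailable: {exc}"
            ) from exc

    def predict_risk(self, df: pd.DataFrame, x: int) -> np.ndarray:
        return expit(self.design(df, x) @ self.params)


def fit_outcome_model(
    table: IPDTable, k, spec: OutcomeModelSpec
) -> OutcomeModelFit:
    """Fit the logistic outcome model on trial ``k``'s rows only."""
    _check_terms_exist(table, spec.rhs(), "outcome model")
    rows = table.rows(k)
    y = rows[OUTCOME].to_numpy(float)
    for arm in (0, 1):
        ya = y[rows[TREATMENT].to_numpy() == arm]
        if ya.size and (ya.sum() == 0 or ya.sum() == ya.size):
            raise DegenerateOutcomeError(
                f"trial {k!r}, arm X={arm}: all outcomes identical "
                f"({int(ya.sum())}/{ya.size} events)"
            )
    dm = patsy.dmatrix(spec.rhs(), rows)
    params = _fit_logit(y, np.asarray(dm), f"outcome model of trial {k!r}")
    return OutcomeModelFit(k, spec, params, dm.design_info, dm.design_info.column_names)


def ocr_standardized_risk(
    model: OutcomeModelFit, table: IPDTable, j, x: int
) -> "StandardizedRisk":
    """Average trial-k model predictions over trial j's covariate records."""
    rows = table.rows(j)
    if rows.empty:
        raise EstimationError(f"target study {j!r} has no rows")
    est = float(model.predict_risk(rows, x).mean())
    return StandardizedRisk(j, model.study, x, est, "OCR")


# ---------------------------------------------------------------------------
# inverse probability weighting
# ---------------------------------------------------------------------------


class PairwisePSFit:
    """Pairwise logistic membership model; ``weight`` returns the fitted odds
    of membership in the target trial j versus the source trial k, i.e. the
    covariate density ratio P(S=j|L)/P(S=k|L)."""

    def __init__(self, j, k, params, design_info):
        self.j, self.k = j, k
        self.params = params
        self.design_info = design_info

    def weight(self, df: pd.DataFrame) -> np.ndarray:
        Z = np.asarray(patsy.build_design_matrices([self.design_info], df)[0])
        return np.exp(np.clip(Z @ self.params, -500.0, 500.0))


class MultinomialPSFit:
    """Multinomial membership model over all K studies (reference: first
    label); pair weights are ratios of predicted membership probabilities."""

    def __init__(self, table: IPDTable, spec: PSModelSpec):
        _check_terms_exist(table, spec.rhs(), "PS model")
        dm = patsy.dmatrix(spec.rhs(), table.data)
        self.design_info = dm.design_info
        self.studies = list(table.studies)
        codes = table.data[STUDY].map({s: i for i, s in enumerate(self.studies)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(codes.to_numpy(), np.asarray(dm)).fit(
                method="newton", maxiter=200, disp=False
            )
        self.params = np.asarray(res.params)  # p x (K-1), reference = code 0
        if not np.all(np.isfinite(self.params)):
            raise PositivityError(
                "multinomial PS fit diverged: a term deterministically "
                "predicts trial membership (deterministic positivity violation)"
            )

    def probabilities(self, df: pd.DataFrame) -> np.ndarray:
        Z = np.asarray(patsy.build_design_matrices([self.design_info], df)[0])
        eta = np.column_stack([np.zeros(len(Z)), Z @ self.params])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)

    def pair(self, j, k) -> "MultinomialPairWeight":
        return MultinomialPairWeight(self, j, k)


class MultinomialPairWeight:
    def __init__(self, fit: MultinomialPSFit, j, k):
        self.fit, self.j, self.k = fit, j, k
        self._ji = fit.studies.index(j)
        self._ki = fit.studies.index(k)

    def weight(self, df: pd.DataFrame) -> np.ndarray:
        p = self.fit.probabilities(df)
        return p[:, self._ji] / p[:, self._ki]


def fit_ps_model(table: IPDTable, j, k, spec: PSModelSpec):
    """Estimate the weight function w(L) = P(S=j|L)/P(S=k|L)."""
    if j == k:
        raise ValueError("PS model requires two distinct trials")
    if spec.mode == "multinomial":
        return MultinomialPSFit(table, spec).pair(j, k)
    _check_terms_exist(table, spec.rhs(), "PS model")
    sub = table.data[table.data[STUDY].isin([j, k])]
    y = (sub[STUDY] == j).to_numpy(float)
    dm = patsy.dmatrix(spec.rhs(), sub)
    try:
        params = _fit_logit(y, np.asarray(dm), f"PS model for pair ({j!r},{k!r})")
    except ConvergenceError as exc:
        raise PositivityError(
            f"membership of trials ({j!r},{k!r}) is perfectly predicted by the "
            "PS terms — a deterministic positivity violation: the trials' "
            "case mixes do not overlap"
        ) from exc
    return PairwisePSFit(j, k, params, dm.design_info)


@dataclass(frozen=True)
class StandardizedRisk:
    """One transported arm-specific risk P{Y(x_k)=1 | S=j}."""

    target_j: object
    source_k: object
    x: int
    estimate: float
    method: str
    weight_summary: WeightSummary | None = None
    boundary_violation: bool = False


def _resolve_weights(table, j, k, weights, rows_k):
    if weights is None:
        if j != k:
            raise EstimationError(
                f"weights required to transport from {k!r} to {j!r}"
            )
        return np.ones(len(rows_k))
    if hasattr(weights, "weight"):
        return np.asarray(weights.weight(rows_k), float)
    w = np.asarray(weights, float)
    if len(w) != len(rows_k):
        raise EstimationError(
            f"weight vector length {len(w)} != trial {k!r} size {len(rows_k)}"
        )
    return w


def ipw_standardized_risk(
    table: IPDTable,
    j,
    k,
    x: int,
    weights=None,
    stabilized: bool = True,
    truncate_q: float | None = None,
    large_weight_threshold: float = LARGE_WEIGHT_THRESHOLD,
    continuity: bool = False,
) -> StandardizedRisk:
    """Weighted transported risk from trial ``k``'s arm ``x`` to population j.

    ``weights`` is a fitted PS object (anything with ``.weight(rows)``), an
    array aligned with trial k's rows, or None for the self-transport j == k
    (unit weights).  The stabilized (Hajek) form divides the weighted event
    sum by the weighted arm size and is invariant to rescaling the weights;
    the unstabilized form divides by the observed arm rate times the target
    sample size and may exceed 1 (flagged, never clipped).
    """
    rows_k = table.rows(k)
    w = _resolve_weights(table, j, k, weights, rows_k)
    if truncate_q is not None:
        w, _ = truncate_weights(w, truncate_q, large_weight_threshold)
    arm = rows_k[TREATMENT].to_numpy() == x
    y = rows_k[OUTCOME].to_numpy(float)
    w_arm = w[arm]
    if w_arm.size == 0 or w_arm.sum() == 0:
        raise EstimationError(
            f"empty effective sample: zero total weight in arm X={x} of trial {k!r}"
        )
    num = float((y[arm] * w_arm).sum())
    summary = WeightSummary.from_weights(w_arm, large_weight_threshold)
    method = "IPW" if stabilized else "IPW-unstabilized"
    if stabilized:
        den = float(w_arm.sum())
        if continuity and (num == 0.0 or num == den):
            wbar = den / w_arm.size
            est = (num + 0.5 * wbar) / (den + wbar)
        else:
            est = num / den
        return StandardizedRisk(j, k, x, est, method, summary)
    arm_rate = float((rows_k[TREATMENT].to_numpy() == x).mean())
    n_j = len(table.rows(j))
    est = num / (arm_rate * n_j)
    return StandardizedRisk(j, k, x, est, method, summary, boundary_violation=est > 1.0)


# ---------------------------------------------------------------------------
# effect measures and the K x K matrix
# ---------------------------------------------------------------------------


@dataclass
class TransportEstimate:
    """One transported effect for the ordered pair (target j, source k)."""

    target_j: object
    source_k: object
    measure: str
    point: float
    log_point: float  # log(RR), log(OR), or the raw RD
    se: float | None = None
    method: str = "OCR"
    diagnostics: dict = field(default_factory=dict)


def effect_measure(
    p1: StandardizedRisk, p0: StandardizedRisk, measure: str = "RR"
) -> TransportEstimate:
    """Combine the two arm risks of one (j, k) cell into an effect measure."""
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    if (p1.target_j, p1.source_k, p1.method) != (p0.target_j, p0.source_k, p0.method):
        raise ValueError("arm risks belong to different (j, k, method) cells")
    if (p1.x, p0.x) != (1, 0):
        raise ValueError("expected the x=1 risk first and the x=0 risk second")
    a, b = p1.estimate, p0.estimate
    if measure == "RD":
        point = a - b
        log_point = point
    elif measure == "RR":
        if b <= 0.0 or a < 0.0:
            raise DegenerateMeasureError(
                f"risk on the boundary (p1={a}, p0={b}): RR undefined; "
                "rerun with continuity correction if appropriate"
            )
        point = a / b
        log_point = float(np.log(point))
    else:  # OR
        if not (0.0 < a < 1.0 and 0.0 < b < 1.0):
            raise DegenerateMeasureError(
                f"risk on the boundary (p1={a}, p0={b}): OR undefined"
            )
        point = (a / (1 - a)) / (b / (1 - b))
        log_point = float(np.log(point))
    diag = {"p1": float(a), "p0": float(b)}
    summaries = [s for s in (p1.weight_summary, p0.weight_summary) if s is not None]
    if summaries:
        diag["max_weight"] = max(s.max for s in summaries)
        diag["min_ess"] = min(s.ess for s in summaries)
        diag["positivity_flag"] = any(s.positivity_flag for s in summaries)
    if p1.boundary_violation or p0.boundary_violation:
        diag["boundary_violation"] = True
    return TransportEstimate(
        p1.target_j, p1.source_k, measure, float(point), float(log_point),
        method=p1.method, diagnostics=diag,
    )


@dataclass
class EffectMatrix:
    """K x K grid of transported effects (row: target j, column: source k)
    with an optional joint covariance of the stacked log effects.

    Stacking order is target-major: entry (j, k) sits at position
    ``j_index * K + k_index`` with studies in first-appearance order.
    """

    measure: str
    studies: list
    estimates: dict = field(default_factory=dict)  # (j,k) -> TransportEstimate
    errors: dict = field(default_factory=dict)  # (j,k) -> str
    covariance: np.ndarray | None = None
    covariance_method: str | None = None
    method: str = "OCR"

    @property
    def K(self) -> int:
        return len(self.studies)

    def index(self, j, k) -> int:
        return self.studies.index(j) * self.K + self.studies.index(k)

    def cell(self, j, k) -> TransportEstimate | None:
        return self.estimates.get((j, k))

    def stacked(self) -> np.ndarray:
        """Stacked log-effect vector; missing cells are NaN."""
        v = np.full(self.K ** 2, np.nan)
        for (j, k), est in self.estimates.items():
            v[self.index(j, k)] = est.log_point
        return v

    def set_covariance(self, sigma: np.ndarray, method: str, tol: float = 1e-8):
        sigma = np.asarray(sigma, float)
        if sigma.shape != (self.K ** 2, self.K ** 2):
            raise ValueError(f"covariance must be {self.K**2}x{self.K**2}")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("covariance is not symmetric")
        if np.linalg.eigvalsh((sigma + sigma.T) / 2).min() < -tol:
            raise ValueError("covariance is not positive semi-definite")
        self.covariance = sigma
        self.covariance_method = method
        for (j, k), est in self.estimates.items():
            i = self.index(j, k)
            est.se = float(np.sqrt(max(sigma[i, i], 0.0)))

    def diagonal(self) -> list:
        return [self.estimates[(s, s)] for s in self.studies if (s, s) in self.estimates]

    def row(self, j) -> list:
        """All estimates transported onto target population j, source order."""
        return [self.estimates[(j, k)] for k in self.studies if (j, k) in self.estimates]

    def column(self, k) -> list:
        return [self.estimates[(j, k)] for j in self.studies if (j, k) in self.estimates]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for j in self.studies:
            for k in self.studies:
                est = self.estimates.get((j, k))
                if est is None:
                    rows.append(
                        {"target_j": j, "source_k": k, "measure": self.measure,
                         "error": self.errors.get((j, k), "missing")}
                    )
                    continue
                d = est.diagnostics
                rows.append(
                    {
                        "target_j": j,
                        "source_k": k,
                        "measure": est.measure,
                        "point": est.point,
                        "log_point": est.log_point,
                        "se": est.se,
                        "max_weight": d.get("max_weight"),
                        "min_ess": d.get("min_ess"),
                        "positivity_flag": d.get("positivity_flag", False),
                        "boundary_violation": d.get("boundary_violation", False),
                        "error": None,
                    }
                )
        return pd.DataFrame(rows)


def estimate_effect_matrix(
    table: IPDTable,
    method: str = "OCR",
    outcome_spec: OutcomeModelSpec | None = None,
    ps_spec: PSModelSpec | None = None,
    measure: str = "RR",
    truncate_q: float | None = None,
    large_weight_threshold: float = LARGE_WEIGHT_THRESHOLD,
    continuity: bool = False,
) -> EffectMatrix:
    """All K^2 transported effects under one estimator configuration.

    Per-cell estimation failures are recorded in ``matrix.errors`` rather
    than aborting the grid; (j, j) cells run through the same machinery
    (unit weights for IPW).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    matrix = EffectMatrix(measure, list(table.studies), method=method)
    stabilized = method != "IPW-unstabilized"

    if method == "OCR":
        if outcome_spec is None:
            raise ValueError("OCR requires an outcome_spec")
        fits = {}
        for k in table.studies:
            try:
                fits[k] = fit_outcome_model(table, k, outcome_spec)
            except EstimationError as exc:
                fits[k] = exc
        # build the forced-treatment design over the whole table once; the
        # per-cell risk is then a masked mean of expit(D_x beta_k)
        some_fit = next((f for f in fits.values() if not isinstance(f, EstimationError)), None)
        D_x = (
            {x: some_fit.design(table.data, x) for x in (0, 1)}
            if some_fit is not None
            else None
        )
        masks = {j: table.mask(j) for j in table.studies}
        for j in table.studies:
            for k in table.studies:
                if isinstance(fits[k], EstimationError):
                    matrix.errors[(j, k)] = str(fits[k])
                    continue
                try:
                    risks = {}
                    for x in (0, 1):
                        est = float(expit(D_x[x][masks[j]] @ fits[k].params).mean())
                        risks[x] = StandardizedRisk(j, k, x, est, "OCR")
                    matrix.estimates[(j, k)] = effect_measure(risks[1], risks[0], measure)
                except EstimationError as exc:
                    matrix.errors[(j, k)] = str(exc)
        return matrix

    if ps_spec is None:
        raise ValueError("IPW requires a ps_spec")
    # shared full-table PS design: one patsy build, one fit per model
    _check_terms_exist(table, ps_spec.rhs(), "PS model")
    Z = np.asarray(patsy.dmatrix(ps_spec.rhs(), table.data))
    masks = {s: table.mask(s) for s in table.studies}
    if ps_spec.mode == "multinomial":
        mn_fit = MultinomialPSFit(table, ps_spec)
        probs = mn_fit.probabilities(table.data)
        sidx = {s: i for i, s in enumerate(table.studies)}
    else:
        mn_fit, probs, sidx = None, None, None
    gammas = {}

    def get_weights(j, k):
        """Per-subject weight array over trial k's rows, or None for j == k."""
        if j == k:
            return None
        if mn_fit is not None:
            return probs[masks[k], sidx[j]] / probs[masks[k], sidx[k]]
        pair = (j, k) if (k, j) not in gammas else (k, j)
        if pair not in gammas:
            m = masks[j] | masks[k]
            try:
                gammas[pair] = _fit_logit(
                    masks[pair[0]][m].astype(float), Z[m],
                    f"PS model for pair ({j!r},{k!r})",
                )
            except ConvergenceError as exc:
                raise PositivityError(
                    f"membership of trials ({j!r},{k!r}) is perfectly predicted "
                    "by the PS terms — a deterministic positivity violation"
                ) from exc
        sign = 1.0 if pair[0] == j else -1.0
        return np.exp(np.clip(sign * (Z[masks[k]] @ gammas[pair]), -500.0, 500.0))

    for j in table.studies:
        for k in table.studies:
            try:
                w = get_weights(j, k)
                common = dict(
                    stabilized=stabilized,
                    truncate_q=truncate_q,
                    large_weight_threshold=large_weight_threshold,
                    continuity=continuity,
                )
                r1 = ipw_standardized_risk(table, j, k, 1, w, **common)
                r0 = ipw_standardized_risk(table, j, k, 0, w, **common)
                matrix.estimates[(j, k)] = effect_measure(r1, r0, measure)
            except EstimationError as exc:
                matrix.errors[(j, k)] = str(exc)
    return matrix
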