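"""Wald chi-square decomposition of heterogeneity.

Stacking the K^2 transported log effects (target-major) as a vector r with
joint covariance Sigma, two families of (K-1)-df contrasts are tested:

* **beyond case-mix** (fixed target j): equality of log RR(j, k) across
  sources k — after standardizing to one case mix, any remaining spread is
  attributable to treatment-version/design differences;
* **case-mix** (fixed source k): equality of log RR(j, k) across targets
  j — one trial's effect moved across case mixes varies only if covariates
  modify the effect.

The statistic is T = (M r)' (M Sigma M')^{-1} (M r) ~ chi^2_{K-1} under the
null.  When M Sigma M' is numerically singular (the estimates can be almost
perfectly correlated when all trials share one case mix), the Moore-Penrose
pseudo-inverse is used with df = rank, and the result is flagged rather
than silently failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .standardize import EffectMatrix

__all__ = ["WaldTest", "build_contrast", "wald_test", "all_wald_tests"]

KINDS = ("beyond-case-mix", "case-mix")

#: condition number above which M Sigma M' is treated as rank-deficient
_COND_LIMIT = 1e12


@dataclass
class WaldTest:
    kind: str
    fixed_index: object  # the fixed target j (beyond-case-mix) or source k
    statistic: float
    df: int
    p_value: float
    contrast: np.ndarray
    rank_deficient: bool = False
    condition_number: float = float("nan")


def build_contrast(K: int, fixed: int, kind: str) -> np.ndarray:
    """(K-1) x K^2 successive-difference contrast on the stacked vector.

    ``fixed`` is the 0-based positional index of the fixed study.  For
    ``beyond-case-mix`` the rows select log RR(j, k) - log RR(j, k+1) within
    the fixed target row j; for ``case-mix``, log RR(j, k) - log RR(j+1, k)
    within the fixed source column k.  Every row sums to zero.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    if K < 2:
        raise ValueError("need K >= 2")
    if not 0 <= fixed < K:
        raise ValueError(f"fixed index {fixed} out of range for K={K}")
    M = np.zeros((K - 1, K * K))
    for r in range(K - 1):
        if kind == "beyond-case-mix":
            a, b = fixed * K + r, fixed * K + r + 1
        else:
            a, b = r * K + fixed, (r + 1) * K + fixed
        M[r, a], M[r, b] = 1.0, -1.0
    return M


def wald_test(matrix: EffectMatrix, fixed, kind: str) -> WaldTest:
    """Test equality of transported effects along one row or column.

    ``fixed`` is a study label of ``matrix``; requires a joint covariance
    (see the variance module) on the matrix.
    """
    if matrix.covariance is None:
        raise EstimationError("effect matrix carries no joint covariance")
    K = matrix.K
    idx = matrix.studies.index(fixed)
    M = build_contrast(K, idx, kind)
    r = matrix.stacked()
    needed = np.any(M != 0.0, axis=0)
    if np.any(~np.isfinite(r[needed])):
        raise EstimationError(
            f"missing transported effects in the {kind} contrast for {fixed!r}"
        )
    r = np.where(np.isfinite(r), r, 0.0)
    d = M @ r
    S = M @ matrix.covariance @ M.T
    cond = float(np.linalg.cond(S))
    rank_deficient = not np.isfinite(cond) or cond > _COND_LIMIT
    if rank_deficient:
        Sinv = np.linalg.pinv(S, rcond=1e-10)
        df = int(np.linalg.matrix_rank(S, tol=None))
        if df == 0:
            raise EstimationError(
                f"degenerate Wald test for {fixed!r}: contrast covariance has "
                f"rank 0 (condition number {cond:.2e})"
            )
    else:
        Sinv = np.linalg.inv(S)
        df = K - 1
    T = float(d @ Sinv @ d)
    T = max(T, 0.0)
    return WaldTest(
        kind=kind,
        fixed_index=fixed,
        statistic=T,
        df=df,
        p_value=float(stats.chi2.sf(T, df)),
        contrast=M,
        rank_deficient=rank_deficient,
        condition_number=cond,
    )


def all_wald_tests(
    matrix: EffectMatrix, bonferroni: bool = False
) -> pd.DataFrame:
    """All 2K tests (K beyond-case-mix, K case-mix) as a tidy report.

    ``bonferroni`` optionally adds a column of p-values adjusted for the
    2K tests; the raw p-values are always reported.
    """
    rows = []
    tests = []
    for kind in KINDS:
        for s in matrix.studies:
            tests.append(wald_test(matrix, s, kind))
    m = len(tests)
    for t in tests:
        row = {
            "kind": t.kind,
            "fixed": t.fixed_index,
            "statistic": t.statistic,
            "df": t.df,
            "p_value": t.p_value,
            "rank_warning": t.rank_deficient,
        }
        if bonferroni:
            row["p_bonferroni"] = min(1.0, t.p_value * m)
        rows.append(row)
    return pd.DataFrame(rows)
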