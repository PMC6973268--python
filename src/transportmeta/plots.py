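"""Simple forest and weight-diagnostic figures (matplotlib)."""

from __future__ import annotations

import numpy as np

from .pooling import PooledResult


def forest_plot(result: PooledResult, ax=None):
    """Forest plot of one population-specific meta-analysis.

    Per-source transported effects with 95% intervals, the pooled diamond
    at the bottom; the x axis is the natural (ratio) scale for RR/OR.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.5 * len(result.sources) + 1.5))
    ratio = result.measure in ("RR", "OR")
    y = result.per_study_effects
    se = result.per_study_se
    ys = np.arange(len(y))[::-1] + 1
    lo, hi = y - 1.96 * se, y + 1.96 * se
    tr = np.exp if ratio else (lambda v: v)
    ax.errorbar(tr(y), ys, xerr=[tr(y) - tr(lo), tr(hi) - tr(y)], fmt="s",
                color="k", capsize=2)
    plo, phi = result.ci95
    ax.errorbar([result.point], [0], xerr=[[result.point - plo], [phi - result.point]],
                fmt="D", color="tab:blue", capsize=2)
    ax.axvline(1.0 if ratio else 0.0, color="grey", lw=0.8, ls="--")
    if ratio:
        ax.set_xscale("log")
    ax.set_yticks(list(ys) + [0])
    ax.set_yticklabels([str(s) for s in result.sources] + ["pooled"])
    ax.set_xlabel(result.measure)
    ax.set_title(f"target population {result.target_j} "
                 f"(tau2={result.tau2:.3f}, I2={result.i2:.0f}%)")
    return ax


def weight_histogram(weights, ax=None, threshold: float = 200.0):
    """Histogram of transport weights with the large-weight threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    w = np.asarray(weights, float)
    ax.hist(np.log10(w[w > 0]), bins=40, color="tab:grey")
    ax.axvline(np.log10(threshold), color="tab:red", ls="--", label=f"w={threshold:g}")
    ax.set_xlabel("log10 weight")
    ax.set_ylabel("subjects")
    ax.legend()
    return ax
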