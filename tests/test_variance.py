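"""Bootstrap and sandwich covariance of the transported log effects."""

import numpy as np
import pandas as pd
import pytest

import transportmeta as tm
from transportmeta.errors import EstimationError
from transportmeta.standardize import PSModelSpec
from transportmeta.variance import (
    bootstrap_covariance,
    pipeline_estimator,
    sandwich_covariance,
    sandwich_se,
)

from conftest import block

OCR_SPEC = tm.OutcomeModelSpec(("L1", "L2", "L3", "L4", "L5"), ("L1",))


def _bernoulli_table(n=1000, p=0.3, seed=4):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {"study": 1, "treatment": rng.integers(0, 2, n),
         "outcome": (rng.random(n) < p).astype(int), "L1": 0.0}
    )
    return tm.IPDTable(df, ["L1"], validate=False)


def test_bootstrap_variance_of_a_binomial_mean():
    table = _bernoulli_table()
    est = lambda t: np.array([t.data["outcome"].mean()])
    cov = bootstrap_covariance(table, est, B=2000, seed=9)
    phat = table.data["outcome"].mean()
    expected = phat * (1 - phat) / table.n
    assert cov.sigma[0, 0] == pytest.approx(expected, rel=0.10)


def test_bootstrap_seed_contract_and_degenerate_estimator():
    table = _bernoulli_table(n=200)
    est = lambda t: np.array([t.data["outcome"].mean()])
    c1 = bootstrap_covariance(table, est, B=50, seed=3)
    c2 = bootstrap_covariance(table, est, B=50, seed=3)
    c3 = bootstrap_covariance(table, est, B=50, seed=4)
    assert np.array_equal(c1.sigma, c2.sigma)
    assert not np.array_equal(c1.sigma, c3.sigma)
    const = bootstrap_covariance(table, lambda t: np.array([1.0, 2.0]), B=50, seed=3)
    assert np.all(const.sigma == 0.0)
    with pytest.raises(ValueError, match="seed"):
        bootstrap_covariance(table, est, B=50, seed=None)


def test_bootstrap_stability_under_doubled_B():
    table = _bernoulli_table(n=500)
    est = lambda t: np.array([t.data["outcome"].mean(),
                              t.data["outcome"][t.data.treatment == 1].mean()])
    c1 = bootstrap_covariance(table, est, B=2000, seed=11)
    c2 = bootstrap_covariance(table, est, B=4000, seed=12)
    assert np.abs(np.diag(c1.sigma) / np.diag(c2.sigma) - 1).max() < 0.10


def test_excessive_replicate_failure_raises():
    table = _bernoulli_table(n=100)

    def flaky(t):
        raise EstimationError("boom")

    with pytest.raises(EstimationError, match="unstable"):
        bootstrap_covariance(table, flaky, B=20, seed=1)


def test_sandwich_matches_bootstrap_setting4(setting4):
    """The two variance routes agree on every cell (within bootstrap noise)."""
    table = tm.generate(setting4, seed=11, n_total=3750)
    sw = sandwich_covariance(table, "OCR", OCR_SPEC)
    bs = bootstrap_covariance(
        table, pipeline_estimator("OCR", OCR_SPEC), B=250, seed=5
    )
    ratio = np.sqrt(np.diag(sw.sigma)) / np.sqrt(np.diag(bs.sigma))
    assert np.all((ratio > 0.85) & (ratio < 1.15))
    # cross-cell correlations also line up (they drive the Wald tests)
    d_s, d_b = np.sqrt(np.diag(sw.sigma)), np.sqrt(np.diag(bs.sigma))
    corr_s = sw.sigma / np.outer(d_s, d_s)
    corr_b = bs.sigma / np.outer(d_b, d_b)
    assert np.abs(corr_s - corr_b).max() < 0.25


def test_sandwich_self_transport_reduces_to_binomial_delta(toy_pair):
    """With unit weights and j = k the IPW sandwich SE of log RR equals the
    delta-method SE for the log ratio of two independent binomials."""
    rows = toy_pair.rows(1)
    p1 = rows[rows.treatment == 1].outcome.mean()
    p0 = rows[rows.treatment == 0].outcome.mean()
    n1 = (rows.treatment == 1).sum()
    n0 = (rows.treatment == 0).sum()
    closed = np.sqrt((1 - p1) / (n1 * p1) + (1 - p0) / (n0 * p0))
    se = sandwich_se(toy_pair, 1, 1, "IPW", ps_spec=PSModelSpec(()))
    assert se == pytest.approx(closed, rel=1e-6)


def test_sandwich_root_n_scaling(setting4):
    t1 = tm.generate(setting4, seed=8, n_total=2000)
    t2 = tm.generate(setting4, seed=8, n_total=8000)
    se1 = sandwich_se(t1, 1, 2, "OCR", outcome_spec=OCR_SPEC)
    se2 = sandwich_se(t2, 1, 2, "OCR", outcome_spec=OCR_SPEC)
    assert se1 / se2 == pytest.approx(2.0, rel=0.2)


def test_sandwich_multinomial_ps_refused(setting4):
    table = tm.generate(setting4, seed=8, n_total=2000)
    with pytest.raises(EstimationError, match="bootstrap"):
        sandwich_covariance(
            table, "IPW", ps_spec=PSModelSpec(("L1",), "multinomial")
        )


def test_covariance_estimate_frame_labels(setting4):
    table = tm.generate(setting4, seed=8, n_total=2000)
    cov = sandwich_covariance(table, "OCR", OCR_SPEC)
    frame = cov.to_frame()
    assert list(frame.columns)[:2] == ["1:1", "1:2"]
    assert np.allclose(frame.to_numpy(), frame.to_numpy().T)


def test_wald_ci_coverage_setting4(setting4):
    """95% Wald intervals on the transported RRs achieve nominal coverage
    (cellwise, averaged over 500 reduced-scale replicates)."""
    truth = tm.true_values(setting4, "quadrature")
    seeds = np.random.SeedSequence(77).spawn(500)
    hits, total = 0, 0
    studies = setting4.studies
    for s in seeds:
        table = tm.generate(setting4, np.random.default_rng(s))
        m = tm.estimate_effect_matrix(table, "OCR", OCR_SPEC)
        cov = sandwich_covariance(table, "OCR", OCR_SPEC)
        m.set_covariance(cov.sigma, "sandwich")
        for j in studies:
            for k in studies:
                est = m.cell(j, k)
                lo = est.log_point - 1.959963984540054 * est.se
                hi = est.log_point + 1.959963984540054 * est.se
                hits += lo <= np.log(truth.rr[(j, k)]) <= hi
                total += 1
    coverage = 100 * hits / total
    assert 92.0 <= coverage <= 98.0
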