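"""Outcome-regression and IPW standardization, effect measures, weights."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

import transportmeta as tm
from transportmeta.errors import (
    DegenerateMeasureError,
    DegenerateOutcomeError,
    EstimationError,
    PositivityError,
)
from transportmeta.standardize import StandardizedRisk, WeightSummary

from conftest import (
    SATURATED_OUTCOME,
    SATURATED_PS,
    block,
    stratified_standardization,
)

HYP = settings(deadline=None, derandomize=True, max_examples=50)


# ---------------------------------------------------------------------------
# outcome model fitting
# ---------------------------------------------------------------------------


def test_saturated_fit_reproduces_stratum_logits(toy_pair):
    fit = tm.fit_outcome_model(toy_pair, 2, SATURATED_OUTCOME)
    rows = toy_pair.rows(2)
    for x in (0, 1):
        for l in (0, 1):
            cell = rows[(rows.treatment == x) & (rows.L1 == l)]
            pred = fit.predict_risk(cell.head(1), x)[0]
            assert pred == pytest.approx(cell.outcome.mean(), abs=1e-8)


def test_null_treatment_effect_estimated_near_zero():
    rng = np.random.default_rng(0)
    n = 5000
    df = pd.DataFrame(
        {"study": np.repeat([1, 2], n // 2),
         "treatment": rng.integers(0, 2, n),
         "outcome": rng.integers(0, 2, n),
         "L1": rng.normal(size=n)}
    )
    fit = tm.fit_outcome_model(tm.IPDTable(df, ["L1"]), 1, SATURATED_OUTCOME)
    b1 = fit.params[fit.param_names.index("treatment")]
    assert abs(b1) < 0.2  # ~3.5 SE at n=2500


def test_parameter_recovery_from_generative_model(setting1):
    # one big draw: each trial ~20k subjects, fit the shared outcome model
    table = tm.generate(setting1, seed=21, n_total=100_000)
    spec = tm.OutcomeModelSpec(("L1", "L2", "L3", "L4", "L5"), ("L1",))
    true = np.array(setting1.outcome["coefficients"])  # 1,X,L1..L5,X:L1
    fit = tm.fit_outcome_model(table, 3, spec)
    # patsy order: Intercept, treatment, mains, treatment:L1
    recovered = np.array(fit.params)
    assert np.abs(recovered - true).max() < 0.15  # ~3 SE at n~20k


def test_degenerate_arm_raises():
    df = pd.concat(
        [block(1, 1, 0, 20, 20), block(1, 0, 0, 20, 7),  # all events in X=1
         block(2, 1, 0, 20, 9), block(2, 0, 0, 20, 8)],
        ignore_index=True,
    )
    with pytest.raises(DegenerateOutcomeError, match="arm X=1"):
        tm.fit_outcome_model(tm.IPDTable(df, ["L1"]), 1, SATURATED_OUTCOME)


def test_perfect_separation_raises_convergence_error():
    # outcome fully determined by L1
    df = pd.concat(
        [block(1, 1, 1, 20, 20), block(1, 0, 1, 20, 20),
         block(1, 1, 0, 20, 0), block(1, 0, 0, 20, 0),
         block(2, 1, 0, 20, 9), block(2, 0, 0, 20, 8)],
        ignore_index=True,
    )
    with pytest.raises(EstimationError):
        tm.fit_outcome_model(tm.IPDTable(df, ["L1"]), 1, SATURATED_OUTCOME)


# ---------------------------------------------------------------------------
# standardized risks: OCR, IPW, and the stratified oracle
# ---------------------------------------------------------------------------


def test_zero_coefficients_give_half(toy_pair):
    fit = tm.fit_outcome_model(toy_pair, 2, SATURATED_OUTCOME)
    fit.params = np.zeros_like(fit.params)
    for j, x in [(1, 0), (1, 1), (2, 0), (2, 1)]:
        assert tm.ocr_standardized_risk(fit, toy_pair, j, x).estimate == pytest.approx(0.5)


def test_toy_pair_triple_agreement(toy_pair):
    """OCR, stabilized IPW and brute-force stratified standardization agree
    exactly on a discrete covariate with saturated models."""
    fit = tm.fit_outcome_model(toy_pair, 2, SATURATED_OUTCOME)
    ps = tm.fit_ps_model(toy_pair, 1, 2, SATURATED_PS)
    for x, expected in [(1, 0.575), (0, 0.35)]:
        ocr = tm.ocr_standardized_risk(fit, toy_pair, 1, x).estimate
        ipw = tm.ipw_standardized_risk(toy_pair, 1, 2, x, ps).estimate
        oracle = stratified_standardization(toy_pair, 1, 2, x)
        assert oracle == pytest.approx(expected, abs=1e-12)
        assert ocr == pytest.approx(oracle, abs=1e-8)
        assert ipw == pytest.approx(oracle, abs=1e-10)


def test_self_transport_with_unit_weights_is_arm_rate(toy_pair):
    rows = toy_pair.rows(2)
    for x in (0, 1):
        risk = tm.ipw_standardized_risk(toy_pair, 2, 2, x)
        assert risk.estimate == pytest.approx(
            rows[rows.treatment == x].outcome.mean()
        )


def test_ps_weight_ratio_closed_form(toy_pair):
    # P(L=1) = 0.5 in trial 1 vs 0.8 in trial 2, equal sizes:
    # w(1)/w(0) = (50/80) / (50/20) = 0.25, exactly at the saturated MLE
    ps = tm.fit_ps_model(toy_pair, 1, 2, SATURATED_PS)
    w = ps.weight(pd.DataFrame({"L1": [1.0, 0.0]}))
    assert w[0] / w[1] == pytest.approx(0.25, abs=1e-8)


def test_disjoint_support_raises_positivity_error():
    df = pd.concat(
        [block(1, 1, 0, 30, 10), block(1, 0, 0, 30, 10),
         block(2, 1, 1, 30, 10), block(2, 0, 1, 30, 10)],
        ignore_index=True,
    )
    with pytest.raises(PositivityError, match="positivity"):
        tm.fit_ps_model(tm.IPDTable(df, ["L1"]), 1, 2, SATURATED_PS)


def test_unstabilized_exceeds_one_stabilized_does_not(adversarial_pair):
    ps = tm.fit_ps_model(adversarial_pair, 1, 2, SATURATED_PS)
    unstab = tm.ipw_standardized_risk(adversarial_pair, 1, 2, 1, ps, stabilized=False)
    stab = tm.ipw_standardized_risk(adversarial_pair, 1, 2, 1, ps, stabilized=True)
    assert unstab.estimate > 1.0 and unstab.boundary_violation
    assert 0.0 <= stab.estimate <= 1.0


@HYP
@given(
    w=st.lists(st.floats(1e-6, 1e6), min_size=2, max_size=40),
    c=st.floats(1e-3, 1e3),
)
def test_stabilized_risk_bounded_and_scale_invariant(w, c):
    """For arbitrary positive weights the Hajek risk stays in [0, 1] and is
    invariant to rescaling all weights."""
    rng = np.random.default_rng(1)
    n = len(w) * 2
    df = pd.concat(
        [block(1, 1, 0, 2, 1), block(1, 0, 0, 2, 1),
         pd.DataFrame({"study": 2, "treatment": rng.integers(0, 2, n),
                       "outcome": rng.integers(0, 2, n), "L1": 0.0})],
        ignore_index=True,
    )
    df.loc[df.study == 2, "treatment"] = [1, 0] * len(w)
    table = tm.IPDTable(df, ["L1"])
    weights = np.repeat(np.asarray(w), 2)
    r = tm.ipw_standardized_risk(table, 1, 2, 1, weights)
    r_scaled = tm.ipw_standardized_risk(table, 1, 2, 1, c * weights)
    assert 0.0 <= r.estimate <= 1.0
    assert r_scaled.estimate == pytest.approx(r.estimate, rel=1e-9)


def test_zero_arm_weight_raises(toy_pair):
    w = np.zeros(len(toy_pair.rows(2)))
    with pytest.raises(EstimationError, match="empty effective sample"):
        tm.ipw_standardized_risk(toy_pair, 1, 2, 1, w)


# ---------------------------------------------------------------------------
# effect measures
# ---------------------------------------------------------------------------


def _risk(p, x, j=1, k=2, method="OCR"):
    return StandardizedRisk(j, k, x, p, method)


def test_effect_measures_closed_form():
    null = tm.effect_measure(_risk(0.35, 1), _risk(0.35, 0), "RR")
    assert null.point == pytest.approx(1.0) and null.log_point == pytest.approx(0.0)
    rr = tm.effect_measure(_risk(0.575, 1), _risk(0.35, 0), "RR")
    assert rr.point == pytest.approx(23 / 14)
    orr = tm.effect_measure(_risk(0.575, 1), _risk(0.35, 0), "OR")
    assert orr.point == pytest.approx((0.575 / 0.425) / (0.35 / 0.65))
    assert orr.log_point == pytest.approx(np.log(2.512605042016807))
    rd = tm.effect_measure(_risk(0.575, 1), _risk(0.35, 0), "RD")
    assert rd.point == pytest.approx(0.225) and rd.log_point == pytest.approx(0.225)


def test_boundary_risks_raise_without_continuity():
    with pytest.raises(DegenerateMeasureError):
        tm.effect_measure(_risk(0.5, 1), _risk(0.0, 0), "RR")
    with pytest.raises(DegenerateMeasureError):
        tm.effect_measure(_risk(1.0, 1), _risk(0.5, 0), "OR")
    with pytest.raises(ValueError, match="different"):
        tm.effect_measure(_risk(0.5, 1, j=1), _risk(0.4, 0, j=2), "RR")


def test_continuity_correction_keeps_measure_finite():
    df = pd.concat(
        [block(1, 1, 0, 20, 5), block(1, 0, 0, 20, 5),
         block(2, 1, 0, 20, 6), block(2, 0, 0, 20, 0)],  # zero control events
        ignore_index=True,
    )
    table = tm.IPDTable(df, ["L1"])
    r0 = tm.ipw_standardized_risk(table, 2, 2, 0, continuity=True)
    assert 0.0 < r0.estimate < 0.1


# ---------------------------------------------------------------------------
# weight truncation
# ---------------------------------------------------------------------------


def test_truncation_order_statistics():
    w, diag = tm.truncate_weights([1.0, 1.0, 1.0, 1000.0], q=0.95)
    # interpolated 95th percentile of (1,1,1,1000) = 1 + 0.85*999
    assert diag.cutoff == pytest.approx(850.15)
    assert w.max() == pytest.approx(850.15) and diag.n_truncated == 1
    assert diag.positivity_flag  # 850.15 > 200


def test_truncation_noop_cases():
    w, diag = tm.truncate_weights(np.full(10, 3.0), q=0.95)
    assert np.all(w == 3.0) and diag.n_truncated == 0 and not diag.positivity_flag
    w2, diag2 = tm.truncate_weights(np.linspace(1, 100, 50), q=0.99)
    assert not diag2.positivity_flag


@HYP
@given(st.lists(st.floats(1e-3, 1e5), min_size=2, max_size=60),
       st.floats(0.05, 0.95))
def test_truncation_properties(w, q):
    out, diag = tm.truncate_weights(w, q)
    assert out.max() <= np.quantile(w, q) + 1e-9
    assert np.all(out <= np.asarray(w) + 1e-12)
    assert np.all(out[np.asarray(w) <= diag.cutoff] == np.asarray(w)[np.asarray(w) <= diag.cutoff])


# ---------------------------------------------------------------------------
# the K x K effect matrix
# ---------------------------------------------------------------------------


def test_toy_pair_effect_matrix_matches_hand_values(toy_pair):
    for method, kwargs in [
        ("OCR", {"outcome_spec": SATURATED_OUTCOME}),
        ("IPW", {"ps_spec": SATURATED_PS}),
    ]:
        m = tm.estimate_effect_matrix(toy_pair, method, measure="RR", **kwargs)
        assert set(m.estimates) == {(1, 1), (1, 2), (2, 1), (2, 2)}
        assert m.cell(1, 2).point == pytest.approx(23 / 14, abs=1e-9)
        oracle_11 = stratified_standardization(toy_pair, 1, 1, 1) / \
            stratified_standardization(toy_pair, 1, 1, 0)
        assert m.cell(1, 1).point == pytest.approx(oracle_11, abs=1e-8)
        v = m.stacked()
        assert v[m.index(1, 2)] == pytest.approx(np.log(23 / 14))


def test_common_law_trials_agree_across_cells(setting4):
    # strip the per-trial treatment effects: one common generative law
    common = tm.SimSetting(
        name="common",
        n_total=setting4.n_total,
        n_trials=setting4.n_trials,
        covariates=list(setting4.covariates),
        covariate_law=setting4.covariate_law,
        membership=setting4.membership,
        outcome={**setting4.outcome, "per_trial": {}},
        treatment_rate=setting4.treatment_rate,
    )
    table = tm.generate(common, seed=3, n_total=10_000)
    spec = tm.OutcomeModelSpec(("L1", "L2", "L3", "L4", "L5"), ("L1",))
    m = tm.estimate_effect_matrix(table, "OCR", spec)
    cov = tm.sandwich_covariance(table, "OCR", spec)
    m.set_covariance(cov.sigma, "sandwich")
    logs = m.stacked()
    ses = np.sqrt(np.diag(cov.sigma))
    assert logs.max() - logs.min() < 4 * ses.max()


def test_failed_cells_flagged_not_fatal():
    df = pd.concat(
        [block(1, 1, 0, 30, 10), block(1, 0, 0, 30, 12),
         block(2, 1, 0, 30, 30), block(2, 0, 0, 30, 5)],  # degenerate arm
        ignore_index=True,
    )
    m = tm.estimate_effect_matrix(
        tm.IPDTable(df, ["L1"]), "OCR", tm.OutcomeModelSpec(("L1",))
    )
    assert (1, 1) in m.estimates and (2, 1) in m.estimates
    assert (1, 2) in m.errors and (2, 2) in m.errors
    assert np.isnan(m.stacked()[m.index(1, 2)])


def test_pairwise_and_multinomial_ps_weights_agree(setting1):
    table = tm.generate(setting1, seed=13, n_total=8000)
    terms = ("L1", "L2", "L3", "L4", "L5", "L1:L2")
    pair = tm.fit_ps_model(table, 1, 3, tm.PSModelSpec(terms, "pairwise"))
    mn = tm.fit_ps_model(table, 1, 3, tm.PSModelSpec(terms, "multinomial"))
    rows = table.rows(3)
    lw_pair = np.log(pair.weight(rows))
    lw_mn = np.log(mn.weight(rows))
    assert np.corrcoef(lw_pair, lw_mn)[0, 1] > 0.98


def test_identical_case_mix_gives_near_constant_weights(setting4):
    table = tm.generate(setting4, seed=17, n_total=10_000)
    ps = tm.fit_ps_model(table, 1, 2, tm.PSModelSpec(("L1", "L2", "L3", "L4", "L5")))
    w = ps.weight(table.rows(2))
    assert w.max() / w.min() < 2.5  # no real signal: weights nearly flat


def test_estimators_consistent_under_correct_specification():
    """With well-overlapping case mixes and ~20k subjects per trial, both
    correctly specified estimators hit every transported risk to <1%
    relative error (30 replicates averaged so residual Monte-Carlo noise
    sits well below the bound)."""
    from transportmeta.benchmark import default_estimators

    setting2 = tm.load_setting("setting2")
    truth2 = tm.true_values(setting2, "mc", mc_draws=5_000_000, seed=321)
    ocr, ipw = default_estimators(setting2)
    acc = {"OCR": [], "IPW": []}
    seeds = np.random.SeedSequence(64).spawn(30)
    for s in seeds:
        table = tm.generate(setting2, np.random.default_rng(s), n_total=100_000)
        for cfg in (ocr, ipw):
            m = tm.estimate_effect_matrix(
                table, cfg.method, cfg.outcome_spec, cfg.ps_spec
            )
            acc[cfg.name].append(
                [[m.cell(j, k).diagnostics["p1"] for k in table.studies]
                 for j in table.studies]
            )
    truth = np.array(
        [[truth2.risk(j, k, 1) for k in setting2.studies]
         for j in setting2.studies]
    )
    for name, draws in acc.items():
        rel = np.abs(np.mean(draws, axis=0) / truth - 1.0)
        assert rel.max() < 0.01, (name, rel.max())


def test_self_transport_converges_to_marginal_effect(setting4):
    """(j, j) cells reproduce the trial's own crude marginal RR as n grows."""
    table = tm.generate(setting4, seed=71, n_total=50_000)
    spec = tm.OutcomeModelSpec(("L1", "L2", "L3", "L4", "L5"), ("L1",))
    m = tm.estimate_effect_matrix(table, "OCR", spec)
    for j in table.studies:
        rows = table.rows(j)
        crude = rows[rows.treatment == 1].outcome.mean() / \
            rows[rows.treatment == 0].outcome.mean()
        assert m.cell(j, j).point == pytest.approx(crude, rel=0.05)
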