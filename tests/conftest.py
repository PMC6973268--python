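"""Shared fixtures: analytic toy datasets and reduced-scale simulation runs."""

import numpy as np
import pandas as pd
import pytest

import transportmeta as tm
from transportmeta.benchmark import default_estimators, run_benchmark


def block(study, x, l, n, events):
    """n subjects in one (study, arm, stratum) cell, `events` of them with Y=1."""
    return pd.DataFrame(
        {"study": study, "treatment": x, "L1": l,
         "outcome": [1] * events + [0] * (n - events)}
    )


def toy_pair_frame() -> pd.DataFrame:
    """Two trials, one binary covariate, chosen so the transported risks
    are exact round numbers: standardizing trial 2's arms over trial 1's
    case mix (P(L=1)=1/2) gives P{Y(1_2)=1|S=1} = 0.575 and
    P{Y(0_2)=1|S=1} = 0.35, hence RR(1,2) = 23/14."""
    parts = [
        # trial 1: 50/50 covariate split, balanced arms, unremarkable outcomes
        block(1, 1, 1, 25, 10), block(1, 0, 1, 25, 8),
        block(1, 1, 0, 25, 5), block(1, 0, 0, 25, 4),
        # trial 2: 80/20 covariate split with the stratum rates 30/40, 4/10, ...
        block(2, 1, 1, 40, 30), block(2, 1, 0, 10, 4),
        block(2, 0, 1, 40, 20), block(2, 0, 0, 10, 2),
    ]
    return pd.concat(parts, ignore_index=True)


@pytest.fixture
def toy_pair() -> tm.IPDTable:
    return tm.IPDTable(toy_pair_frame(), ["L1"])


def stratified_standardization(table, j, k, x):
    """Brute-force oracle: sum_l P(Y=1|X=x, L=l, S=k) P(L=l | S=j)."""
    rows_j, rows_k = table.rows(j), table.rows(k)
    total = 0.0
    for l, p_l in rows_j["L1"].value_counts(normalize=True).items():
        cell = rows_k[(rows_k["treatment"] == x) & (rows_k["L1"] == l)]
        total += p_l * cell["outcome"].mean()
    return total


SATURATED_OUTCOME = tm.OutcomeModelSpec(main_terms=("L1",), treatment_interactions=("L1",))
SATURATED_PS = tm.PSModelSpec(terms=("L1",))


@pytest.fixture
def adversarial_pair() -> tm.IPDTable:
    """Near-disjoint case mixes: trial 2 holds a single L=1 subject whose
    transport weight toward trial 1 (P(L=1) = 0.99) is enormous, so the
    unstabilized IPW risk exceeds 1 while the stabilized one cannot."""
    parts = [
        block(1, 1, 1, 49, 20), block(1, 0, 1, 50, 20), block(1, 1, 0, 1, 0),
        block(2, 1, 1, 1, 1), block(2, 1, 0, 49, 10), block(2, 0, 0, 50, 10),
    ]
    return tm.IPDTable(pd.concat(parts, ignore_index=True), ["L1"])


# ---------------------------------------------------------------------------
# simulation fixtures (session-scoped: shared across acceptance tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def setting1():
    return tm.load_setting("setting1")


@pytest.fixture(scope="session")
def setting3():
    return tm.load_setting("setting3")


@pytest.fixture(scope="session")
def setting4():
    return tm.load_setting("setting4")


@pytest.fixture(scope="session")
def setting5():
    return tm.load_setting("setting5")


@pytest.fixture(scope="session")
def setting1_truth(setting1):
    """Monte-Carlo truth oracle for setting 1 (5e6 draws)."""
    return tm.true_values(setting1, "mc", mc_draws=5_000_000, seed=123)


@pytest.fixture(scope="session")
def setting1_ocr_benchmark(setting1, setting1_truth):
    """500 replicates of setting 1 with correctly specified OCR: serves the
    bias, heterogeneity-decomposition and type-I-error checks."""
    ocr = [e for e in default_estimators(setting1) if e.name == "OCR"]
    return run_benchmark(setting1, ocr, replicates=500, seed=42, truth=setting1_truth)
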