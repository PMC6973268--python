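"""Subject-level multi-trial data: container, validation, I/O, descriptives.

An :class:`IPDTable` holds one row per randomized participant with a trial
label ``study`` (S), binary ``treatment`` (X), binary ``outcome`` (Y) and a
named vector of numeric baseline covariates L.  Study labels keep their
first-appearance order, and every K x K object downstream (effect matrices,
covariances, contrasts) is indexed in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

__all__ = ["IPDTable", "StudyMeta", "read_ipd", "write_ipd", "study_meta"]

#: canonical column names used internally
STUDY, TREATMENT, OUTCOME, SUBJECT = "study", "treatment", "outcome", "subject_id"


@dataclass
class IPDTable:
    """Validated rectangular IPD: one row per randomized participant.

    Parameters
    ----------
    data
        Frame with columns ``subject_id``, ``study``, ``treatment``,
        ``outcome`` plus one numeric column per covariate.
    covariates
        Names of the baseline covariate columns, identical across studies.
    validate
        Skip invariant checks when False (used internally for bootstrap
        resamples, which may transiently violate e.g. the two-arm rule).
    """

    data: pd.DataFrame
    covariates: list[str]
    validate: bool = True
    studies: list = field(init=False)

    def __post_init__(self):
        df = self.data
        required = [STUDY, TREATMENT, OUTCOME, *self.covariates]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
        if SUBJECT not in df.columns:
            df = df.copy()
            df[SUBJECT] = np.arange(len(df))
            self.data = df
        # first-appearance order of the study labels
        self.studies = list(pd.unique(df[STUDY]))
        if self.validate:
            self._check_invariants()

    def _check_invariants(self):
        df = self.data
        if len(self.studies) < 2:
            raise DataError(f"need at least 2 studies, found {len(self.studies)}")
        for col in (STUDY, TREATMENT, OUTCOME):
            if df[col].isna().any():
                rows = df.index[df[col].isna()].tolist()[:10]
                raise DataError(f"missing values in '{col}' (rows {rows})")
        for col in (TREATMENT, OUTCOME):
            vals = pd.unique(df[col])
            bad = [v for v in vals if v not in (0, 1)]
            if bad:
                rows = df.index[df[col].isin(bad)].tolist()[:10]
                raise DataError(
                    f"'{col}' must be coded 0/1; found {bad} (rows {rows})"
                )
        for cov in self.covariates:
            if df[cov].isna().any():
                rows = df.index[df[cov].isna()].tolist()[:10]
                raise DataError(
                    f"missing covariate values in '{cov}' (rows {rows}); "
                    "complete IPD is required"
                )
            if not pd.api.types.is_numeric_dtype(df[cov]):
                raise DataError(f"covariate '{cov}' is not numeric")
        for s in self.studies:
            arms = set(pd.unique(df.loc[df[STUDY] == s, TREATMENT]))
            if arms != {0, 1}:
                raise DataError(
                    f"study {s!r} does not contain both treatment arms (has {sorted(arms)})"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def K(self) -> int:
        return len(self.studies)

    def rows(self, study) -> pd.DataFrame:
        """All rows of one study, original order preserved."""
        if study not in self.studies:
            raise DataError(f"unknown study label {study!r}")
        return self.data[self.data[STUDY] == study]

    def mask(self, study) -> np.ndarray:
        return (self.data[STUDY] == study).to_numpy()

    def resample_within_studies(self, rng: np.random.Generator) -> "IPDTable":
        """Nonparametric bootstrap draw: subjects with replacement per study,
        preserving each study's size (trials are fixed by design)."""
        parts = []
        for s in self.studies:
            block = self.data[self.data[STUDY] == s]
            idx = rng.integers(0, len(block), len(block))
            parts.append(block.iloc[idx])
        df = pd.concat(parts, ignore_index=True)
        return IPDTable(df, list(self.covariates), validate=False)


@dataclass(frozen=True)
class StudyMeta:
    """Per-trial descriptives: arm counts, randomization ratio Rk, arm rate."""

    study: object
    n: int
    n_treated: int
    n_control: int
    rk: float  # n_treated / n_control
    arm_rate: float  # observed P(X=1 | S=k)


def study_meta(table: IPDTable) -> list[StudyMeta]:
    """One :class:`StudyMeta` per study, in label order; exact rational counts."""
    out = []
    for s in table.studies:
        x = table.rows(s)[TREATMENT].to_numpy()
        n1 = int(x.sum())
        n0 = int(len(x) - n1)
        out.append(StudyMeta(s, len(x), n1, n0, n1 / n0, n1 / len(x)))
    return out


def read_ipd(
    path,
    schema: Mapping[str, object] | None = None,
    covariates: Sequence[str] | None = None,
    sep: str | None = None,
) -> IPDTable:
    """Read delimited IPD with a header row.

    ``schema`` maps canonical names (``study``, ``treatment``, ``outcome``,
    optionally ``subject_id``) to the file's column names and must carry a
    ``covariates`` list (or pass ``covariates=`` separately).  Without a
    schema the file is expected to already use canonical column names.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    schema = dict(schema or {})
    covs = list(schema.pop("covariates", covariates or []))
    if not covs:
        covs = [c for c in df.columns if c not in (STUDY, TREATMENT, OUTCOME, SUBJECT)]
        if not covs:
            raise SchemaError("no covariate columns declared or inferable")
    rename = {}
    for canonical in (STUDY, TREATMENT, OUTCOME, SUBJECT):
        src = schema.get(canonical, canonical)
        if canonical in (STUDY, TREATMENT, OUTCOME) and src not in df.columns:
            raise SchemaError(f"column {src!r} (mapped to {canonical!r}) not in file")
        if src in df.columns:
            rename[src] = canonical
    missing_cov = [c for c in covs if c not in df.columns]
    if missing_cov:
        raise SchemaError(f"covariate columns not in file: {missing_cov}")
    return IPDTable(df.rename(columns=rename), covs)


def write_ipd(table: IPDTable, path, sep: str | None = None) -> None:
    """Write in the same dialect ``read_ipd`` accepts (UTF-8, header row)."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    cols = [SUBJECT, STUDY, TREATMENT, OUTCOME, *table.covariates]
    table.data[cols].to_csv(path, sep=sep, index=False)
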