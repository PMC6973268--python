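"""YAML run configuration for the command-line interface.

A run config names exactly one input source (a delimited IPD file with its
column schema, or a simulation setting), the estimator (method, effect
measure, model formulas, optional weight truncation), and the variance
method.  A seed is mandatory whenever any stochastic step (simulation or
bootstrap) is enabled.  Schema::

    input:                      # either this ...
      path: ipd.csv
      study: trial              # column mapping (canonical: study,
      treatment: arm            #   treatment, outcome, subject_id)
      outcome: y
      covariates: [age, sex]
    simulate:                   # ... or this
      setting: setting1         # builtin name or YAML path
      n_total: 3750             # optional override
    estimator:
      method: OCR               # OCR | IPW | IPW-unstabilized
      measure: RR               # RR | OR | RD
      outcome_model:
        main_terms: [age, sex]
        treatment_interactions: [age]
        extra_terms: ["I(age**2)"]
      ps_model:
        terms: [age, sex, "age:sex"]
        mode: pairwise          # pairwise | multinomial
      truncation:               # application profile: on with q=0.95
        q: 0.95
        threshold: 200
      continuity: false
    variance:
      method: bootstrap         # bootstrap | sandwich | none
      B: 1000
      seed: 1                   # falls back to the top-level seed
    seed: 1
    output: results/
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .ipd import IPDTable, read_ipd
from .simulate import generate, load_setting
from .standardize import OutcomeModelSpec, PSModelSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    estimator: dict
    input: dict | None = None
    simulate: dict | None = None
    variance: dict | None = None
    seed: int | None = None
    output: str = "."
    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.input is None) == (self.simulate is None):
            raise ConfigError("config must name exactly one of 'input' or 'simulate'")
        method = self.estimator.get("method", "OCR")
        if method in ("OCR",) and "outcome_model" not in self.estimator:
            raise ConfigError("OCR requires estimator.outcome_model")
        if method.startswith("IPW") and "ps_model" not in self.estimator:
            raise ConfigError("IPW requires estimator.ps_model")
        if self.simulate is not None and self.seed is None:
            raise ConfigError("simulation input requires a seed")
        if self.variance and self.variance.get("method") == "bootstrap":
            if self.variance.get("seed", self.seed) is None:
                raise ConfigError("bootstrap variance requires a seed")

    # -- derived objects -----------------------------------------------------

    def load_table(self) -> IPDTable:
        if self.input is not None:
            spec = dict(self.input)
            path = spec.pop("path", None)
            if path is None:
                raise ConfigError("input.path is required")
            sep = spec.pop("sep", None)
            return read_ipd(path, schema=spec, sep=sep)
        sim = dict(self.simulate)
        setting = load_setting(sim["setting"])
        return generate(setting, seed=self.seed, n_total=sim.get("n_total"))

    def outcome_spec(self) -> OutcomeModelSpec | None:
        om = self.estimator.get("outcome_model")
        if om is None:
            return None
        return OutcomeModelSpec(
            main_terms=tuple(om.get("main_terms", ())),
            treatment_interactions=tuple(om.get("treatment_interactions", ())),
            extra_terms=tuple(om.get("extra_terms", ())),
        )

    def ps_spec(self) -> PSModelSpec | None:
        ps = self.estimator.get("ps_model")
        if ps is None:
            return None
        return PSModelSpec(
            terms=tuple(ps.get("terms", ())), mode=ps.get("mode", "pairwise")
        )

    def estimator_options(self) -> dict:
        trunc = self.estimator.get("truncation")
        opts = {"continuity": bool(self.estimator.get("continuity", False))}
        if trunc:
            opts["truncate_q"] = float(trunc.get("q", 0.95))
            opts["large_weight_threshold"] = float(trunc.get("threshold", 200))
        return opts


def load_config(path) -> RunConfig:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict) or "estimator" not in raw:
        raise ConfigError("config must be a mapping with an 'estimator' section")
    return RunConfig(
        estimator=raw["estimator"],
        input=raw.get("input"),
        simulate=raw.get("simulate"),
        variance=raw.get("variance"),
        seed=raw.get("seed"),
        output=raw.get("output", "."),
        raw=raw,
    )
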