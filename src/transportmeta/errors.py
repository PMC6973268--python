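"""Exception hierarchy.

Every error raised by the package derives from :class:`TransportMetaError`;
the ``exit_code`` attribute is what the CLI returns, so callers can
distinguish configuration problems (2) from data problems (3) and
estimation failures (4).
"""


class TransportMetaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(TransportMetaError):
    """Invalid or inconsistent run configuration."""

    exit_code = 2


class SchemaError(TransportMetaError):
    """Input data do not match the declared column schema."""

    exit_code = 3


class DataError(TransportMetaError):
    """Structurally invalid subject-level data (coding, arms, missingness)."""

    exit_code = 3


class EstimationError(TransportMetaError):
    """An estimator could not produce a usable result."""

    exit_code = 4


class ConvergenceError(EstimationError):
    """Model fitting failed to converge (e.g. perfect separation)."""


class DegenerateOutcomeError(EstimationError):
    """A trial arm contains only events or only non-events."""


class DegenerateMeasureError(EstimationError):
    """A risk on the boundary {0, 1} makes the requested effect measure undefined."""


class PositivityError(EstimationError):
    """Deterministic positivity violation: a term perfectly predicts trial membership."""
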