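"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ThcDosimError` so callers can
distinguish pipeline failures from programming errors.
"""


class ThcDosimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThcDosimError):
    """Invalid simulation or run configuration."""


class DataError(ThcDosimError):
    """Input data violate a schema or physical invariant (e.g. a gelatin
    cup that gained mass beyond the evaporation tolerance)."""


class DegenerateDesignError(ThcDosimError):
    """Too few distinct dose levels / constant predictor: the requested
    fit or test is not identifiable."""


class NotConvergedError(ThcDosimError):
    """A downstream operation was asked to use a flagged (non-converged
    or unidentifiable) fit."""


class OutOfRangeError(ThcDosimError):
    """An observed response lies outside the dynamic range of the fitted
    curve, or inversion would extrapolate beyond the permitted dose range."""
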