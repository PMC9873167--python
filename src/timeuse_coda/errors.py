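"""Exception hierarchy.

Validation problems (bad inputs, bad configuration) exit with code 2 from the
CLI; estimation problems (rank deficiency, failed bootstrap, impossible
reweighting) exit with code 3.
"""


class TimeUseCodaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(TimeUseCodaError):
    exit_code = 2


class InvalidCompositionError(ValidationError):
    """A vector of parts cannot form a valid composition."""


class ConfigurationError(ValidationError):
    """Bad basis, activity map, or generator configuration."""


class ClassificationError(ValidationError):
    """An activity code could not be resolved to a behaviour category."""


class MalformedDiaryError(ValidationError):
    """A diary does not consist of 144 uniquely-indexed 10-minute slots."""


class UsageError(ValidationError):
    """API misuse: unknown variable/category, basis mismatch, and similar."""


class EstimationError(TimeUseCodaError):
    exit_code = 3


class WeightingError(EstimationError):
    """Day-of-week uniformisation is impossible (a day is absent)."""


class BootstrapError(EstimationError):
    """Too many bootstrap replicates failed to produce an estimate."""
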