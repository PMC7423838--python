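"""Exception hierarchy.

Validation-type errors (bad inputs, malformed files, bad config) map to CLI
exit code 1; everything else raised by the package maps to exit code 2.
"""


class NtcpError(Exception):
    """Base class for all package errors."""


class ParameterError(NtcpError, ValueError):
    """A function argument is outside its documented domain."""


class ValidationError(NtcpError, ValueError):
    """Input data violate a documented invariant."""


class SchemaError(ValidationError):
    """A file or config is missing required columns/keys."""


class ConfigurationError(ValidationError):
    """A configuration value is inconsistent or refers to a missing feature."""


class StateError(NtcpError):
    """An operation was applied to an object in the wrong state."""


class DataError(NtcpError):
    """Required data are absent or inconsistent at computation time."""


class DegenerateOutcomeError(DataError):
    """The outcome vector contains a single class."""


class UndefinedStatisticError(DataError):
    """A statistic is undefined for the given input (e.g. constant vector)."""


class ConsistencyError(NtcpError):
    """Artifacts from different runs were combined."""


#: Errors that indicate bad user input rather than an internal failure.
VALIDATION_ERRORS = (ParameterError, ValidationError)
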