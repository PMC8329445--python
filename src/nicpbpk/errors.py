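"""Exception hierarchy shared across the package."""


class NicPBPKError(Exception):
    """Base class for all package errors."""


class DomainError(NicPBPKError, ValueError):
    """An argument is outside its physically meaningful domain."""


class ConfigurationError(NicPBPKError, ValueError):
    """A configuration document is malformed or inconsistent.

    The message names the offending field.
    """


class CalibrationError(NicPBPKError, RuntimeError):
    """A calibration target cannot be reached with admissible parameters."""


class NumericalError(NicPBPKError, RuntimeError):
    """The ODE solver produced a non-finite state or failed to converge."""
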