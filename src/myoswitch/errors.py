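"""Exception hierarchy.

All package errors derive from :class:`SwitchModelError` and, where the
failure is a bad argument, also from :class:`ValueError`, so callers can
catch either.
"""


class SwitchModelError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(SwitchModelError, ValueError):
    """A model parameter violates its invariant (e.g. negative rate)."""


class DomainError(SwitchModelError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigurationError(SwitchModelError, ValueError):
    """A configuration file or config object is invalid."""


class FormatError(SwitchModelError, ValueError):
    """A data file does not match the expected on-disk format."""


class UndefinedResultError(SwitchModelError, ValueError):
    """The requested quantity is undefined for this input (e.g. n < 2)."""


class UndefinedCorrelationError(UndefinedResultError):
    """Correlation undefined because one input has zero variance."""
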