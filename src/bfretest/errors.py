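"""Exception hierarchy. Everything raised on purpose derives from RetestError."""

from __future__ import annotations

__all__ = [
    "RetestError",
    "SchemaError",
    "RowValidationError",
    "DomainError",
    "PreconditionError",
    "NumericError",
    "ConfigError",
]


class RetestError(Exception):
    """Base class for all package errors."""


class SchemaError(RetestError):
    """The extraction sheet is structurally wrong (e.g. a missing column)."""


class RowValidationError(RetestError):
    """A data row violates the record schema; message carries row diagnostics."""


class DomainError(RetestError):
    """An argument is outside the mathematical domain of an operation."""


class PreconditionError(RetestError):
    """A record lacks the fields an operation requires; message names them."""


class NumericError(RetestError):
    """Numerical integration failed its accuracy target."""


class ConfigError(RetestError):
    """A configuration object is inconsistent."""
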