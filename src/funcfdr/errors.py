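"""Exception hierarchy for funcfdr.

All package-raised errors derive from :class:`FuncFdrError` so callers can
catch one type at the CLI boundary.
"""


class FuncFdrError(Exception):
    """Base class for all funcfdr errors."""


class InvalidInputError(FuncFdrError, ValueError):
    """Malformed numeric input (non-finite values, empty collections, ...)."""


class SchemaError(FuncFdrError, ValueError):
    """An input table is missing a required column."""


class ValidationError(FuncFdrError, ValueError):
    """A table row violates a value constraint (e.g. p-value outside [0,1])."""


class AlignmentError(FuncFdrError, ValueError):
    """Two per-test collections that must be index-aligned have different lengths."""


class InvalidTuningError(FuncFdrError, ValueError):
    """A tuning parameter (lambda, alpha, grid) is outside its admissible range."""


class FitFailureError(FuncFdrError, RuntimeError):
    """A maximum-likelihood fit failed to converge (e.g. complete separation)."""


class InsufficientDataError(FuncFdrError, ValueError):
    """Too few observations remain for the requested estimator."""


class EstimationError(FuncFdrError, RuntimeError):
    """Density estimation received degenerate input."""


class DomainError(FuncFdrError, ValueError):
    """Evaluation requested outside the estimator's domain."""


class ConfigurationError(FuncFdrError, ValueError):
    """A simulation specification names an unsupported functional form."""
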