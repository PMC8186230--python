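"""Exception hierarchy.

All package errors derive from :class:`AppsigError` so callers (and the CLI)
can distinguish validation problems from genuine bugs.
"""


class AppsigError(Exception):
    """Base class for all errors raised by appsig."""


class ValidationError(AppsigError, ValueError):
    """Input violates a documented invariant (bad shape, value, or config)."""


class StructuralError(ValidationError):
    """A file or table is malformed: duplicates, bad header, non-numeric cell."""


class CrossReferenceError(ValidationError):
    """An identifier refers to an entity that does not exist in its companion."""


class SchemaError(ValidationError):
    """Column/field mismatch between a model and the data it is applied to."""


class NumericalError(AppsigError, ArithmeticError):
    """A numerical procedure failed (non-convergence treated as fatal, etc.)."""
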