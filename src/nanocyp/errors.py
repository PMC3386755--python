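"""Exception hierarchy shared across the package."""


class NanocypError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NanocypError, ValueError):
    """A parameter violates a documented precondition."""


class InsufficientDataError(NanocypError, ValueError):
    """Too few samples / points to carry out the requested computation."""


class EmptyStateError(NanocypError, ValueError):
    """An operation that needs adsorbed proteins was given an empty state."""


class FormatError(NanocypError, ValueError):
    """A data file does not conform to the expected column layout."""


class ValidationError(NanocypError, ValueError):
    """Parsed data violates a physical invariant (range, monotonicity)."""
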