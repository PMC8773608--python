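"""Exception hierarchy shared across the package.

All magcomp-specific failures derive from :class:`MagcompError` so callers
can catch the package's errors without masking programming mistakes.
"""


class MagcompError(Exception):
    """Base class for all magcomp errors."""


class InvalidArgumentError(MagcompError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateModelError(MagcompError):
    """The observer or contrast is degenerate (e.g. zero decision noise)."""


class InsufficientDataError(MagcompError):
    """Too few levels or trials to perform the requested fit or split."""


class SchemaError(MagcompError):
    """A trial table or config does not match the canonical schema."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class NumericalFailureError(MagcompError):
    """A numerical routine (integration, optimisation) failed to converge."""
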