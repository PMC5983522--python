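"""Exception hierarchy for coredeg.

All errors raised by the package derive from :class:`CoredegError` so callers
can catch one type at pipeline boundaries. ``DomainError`` additionally
subclasses ``ValueError`` because it signals invalid numeric arguments.
"""


class CoredegError(Exception):
    """Base class for all coredeg errors."""


class FormatError(CoredegError):
    """An input file does not match the declared dialect or schema."""


class ValidationError(CoredegError):
    """Input parsed but violates a data invariant (duplicates, bad values)."""


class DomainError(CoredegError, ValueError):
    """A numeric argument lies outside the operation's domain."""


class PipelineError(CoredegError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
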