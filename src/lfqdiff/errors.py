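"""Exception hierarchy."""


class LfqDiffError(Exception):
    """Base class for all package errors."""


class FormatError(LfqDiffError):
    """An input file does not have the expected layout."""


class ValidationError(LfqDiffError, ValueError):
    """Input data violates an invariant (negative intensity, all-zero sample, ...)."""


class UsageError(LfqDiffError, ValueError):
    """An operation was called with inconsistent arguments."""
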