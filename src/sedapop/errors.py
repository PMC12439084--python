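"""Exception hierarchy shared across the pipeline.

Each class maps to a distinct CLI exit code (see :mod:`sedapop.cli`).
"""


class SedapopError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class FormatError(SedapopError):
    """A file could not be parsed as the format it claims to be."""

    exit_code = 2


class EmptyDataError(SedapopError):
    """An input was syntactically valid but contained no usable data."""

    exit_code = 3


class ValidationError(SedapopError):
    """Parsed values violate an invariant (range, uniqueness, monotonicity)."""

    exit_code = 4


class AnalysisError(SedapopError):
    """A statistical operation was called on inputs it is undefined for."""

    exit_code = 5
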