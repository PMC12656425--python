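"""Exception hierarchy shared across the toolkit.

Exit-code mapping used by the CLI: validation errors -> 2, missing
dependencies between pipeline stages -> 3, runtime failures -> 4.
"""


class VoxfuseError(Exception):
    """Base class for all package errors."""

    exit_code = 4


class ValidationError(VoxfuseError):
    """Invalid configuration or input that violates a documented invariant."""

    exit_code = 2


class DependencyError(VoxfuseError):
    """A pipeline stage was invoked before the artifacts it needs exist."""

    exit_code = 3


class EmptyInputError(ValidationError):
    """An operation received an empty signal or table."""


class NoVoicingError(VoxfuseError):
    """No voiced frames were found where voicing is required."""
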