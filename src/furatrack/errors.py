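"""Typed error hierarchy shared by all pipeline stages.

Every reader and operation rejects malformed input with one of these
exception classes rather than silently coercing; the CLI maps them to
distinct exit codes.
"""


class PipelineError(Exception):
    """Base class for all furatrack errors."""


class ValidationError(PipelineError, ValueError):
    """A parameter or input violates a documented precondition."""


class ShapeError(ValidationError):
    """Array inputs disagree in shape or frame count."""


class FormatError(PipelineError):
    """A file could not be parsed as the expected format."""


class DegenerateInputError(PipelineError):
    """Input is structurally valid but scientifically empty
    (e.g. an all-zero field of view, an empty ROI)."""
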