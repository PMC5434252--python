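"""Exception hierarchy.

Exit-code mapping used by the CLI: validation failures (schema, record,
content, rating input) map to exit code 1, I/O problems to exit code 2.
"""


class SDRecError(Exception):
    """Base class for all package errors."""


class SchemaValidationError(SDRecError):
    """A minimum-dataset document violates the schema contract."""


class RecordValidationError(SDRecError):
    """A medical record or visit violates an invariant or the MDS."""


class ContentValidationError(SDRecError):
    """A content-library document is malformed or inconsistent with the MDS."""


class ConditionError(SDRecError):
    """An applicability condition is malformed."""


class TailoringError(SDRecError):
    """Slot filling failed (strict mode, missing value) or a degenerate range."""


class RatingError(SDRecError):
    """Checklist ratings are malformed, mixed-family, or incomplete."""
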