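"""Exception hierarchy.

All user-facing failures derive from :class:`RiskPatternError` so the CLI can
map them to exit code 1; anything else is an internal error (exit code 2).
"""


class RiskPatternError(Exception):
    """Base class for user-facing errors."""


class SchemaError(RiskPatternError):
    """A variable schema is malformed or does not match the data."""


class ValidationError(RiskPatternError):
    """Input data violates a contract (bad target value, parse failure, ...)."""


class PatternFormatError(RiskPatternError):
    """A pattern JSON document is malformed; the message names the field."""


class EditError(RiskPatternError):
    """A pattern edit is inconsistent with the pattern or the schema."""
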