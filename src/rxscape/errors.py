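"""Exception hierarchy for rxscape.

All errors raised by the library derive from :class:`RxscapeError` so callers
can catch one base class at pipeline boundaries.
"""


class RxscapeError(Exception):
    """Base class for all rxscape errors."""


class ValidationError(RxscapeError, ValueError):
    """A parameter or configuration value violates its contract."""


class SchemaError(RxscapeError, ValueError):
    """An input table is missing a required column or has the wrong dtype."""


class IntegrityError(RxscapeError, ValueError):
    """Input data violates a structural invariant (e.g. duplicate keys)."""


class MappingError(RxscapeError, KeyError):
    """A drug (or other key) has no entry in a required mapping."""
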