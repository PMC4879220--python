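"""Exception hierarchy shared across the toolkit."""


class OrsimError(Exception):
    """Base class for all toolkit errors."""


class DomainError(OrsimError, ValueError):
    """A value is outside the operation's domain (e.g. zero-length scenario)."""


class LengthMismatchError(DomainError):
    """Parameter tracks of unequal length were combined into one script."""


class SchemaError(OrsimError, KeyError):
    """A reference to an unknown parameter, alarm ID, or column."""


class ValidationError(OrsimError, ValueError):
    """File or table content violates the documented layout or value ranges."""


class MissingDataError(ValidationError):
    """A rating design has missing cells and no missing-data policy was given."""
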