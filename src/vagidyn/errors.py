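"""Exception hierarchy shared across the package."""


class VagidynError(Exception):
    """Base class for all package errors."""


class ParseError(VagidynError):
    """A file cell could not be interpreted (non-numeric, negative count, bad token)."""


class FormatError(VagidynError):
    """A file violates its structural contract (duplicate ids, missing columns)."""


class ValidationError(VagidynError):
    """An in-memory object violates a domain invariant."""


class UsageError(VagidynError):
    """An operation was called with arguments outside its contract."""
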