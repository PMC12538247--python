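"""Exception types shared across the package."""


class EegAffectError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EegAffectError, ValueError):
    """An argument or data value violates a documented contract."""


class FormatError(EegAffectError, ValueError):
    """An on-disk file does not match the expected layout."""
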