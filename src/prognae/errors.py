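"""Exception types shared across the package."""


class PrognaeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PrognaeError, ValueError):
    """A file does not conform to the expected format (missing header,
    wrong column count, unparsable cell)."""


class ValidationError(PrognaeError, ValueError):
    """Parsed content violates a domain invariant (duplicate ids,
    negative survival time, start > end, ...)."""
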