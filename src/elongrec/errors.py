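"""Exception types shared across the package."""


class ElongrecError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ElongrecError):
    """A file does not conform to its declared dialect (GTF, TSV, YAML)."""


class ValidationError(ElongrecError):
    """Structurally parseable input that violates a domain invariant."""


class ParameterError(ElongrecError):
    """An operation was called with inconsistent or out-of-range parameters."""
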