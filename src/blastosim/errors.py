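"""Exception types shared across the package."""


class BlastosimError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BlastosimError):
    """A configuration or domain object violates its invariants.

    The message always names the offending field.
    """


class OutOfDomainError(BlastosimError):
    """A physical coordinate lies outside the embryo interior."""


class SchemaError(BlastosimError):
    """A track table violates the lineage/track schema."""


class FitError(BlastosimError):
    """A model fit failed; the message carries optimizer diagnostics."""
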