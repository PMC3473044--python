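"""Exception hierarchy shared across the package."""


class SeedshiftError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SeedshiftError, ValueError):
    """A token or file could not be parsed; the message names the offender."""


class ValidationError(SeedshiftError, ValueError):
    """Input parsed but violates a domain invariant."""


class ReferenceMismatchError(ValidationError):
    """A mutation's reference allele disagrees with the stored UTR sequence."""


class PipelineError(SeedshiftError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
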