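"""Exception hierarchy shared by all pipeline stages."""


class CallihybError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CallihybError):
    """A file or notation string could not be parsed."""


class ValidationError(CallihybError):
    """Parsed data violates a domain invariant (vocabulary, uniqueness, range)."""


class ConfigurationError(CallihybError):
    """A configuration is internally inconsistent or infeasible."""


class SequenceIdentityError(CallihybError):
    """A query sequence does not look like the expected locus.

    Raised when a putative SRY amplicon or COX2 read falls below the
    identity threshold against every reference it is compared to.
    """
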