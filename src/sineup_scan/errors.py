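"""Exception hierarchy for the screening and design toolkit."""


class SineupError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SineupError):
    """A line of an input file could not be parsed."""

    def __init__(self, message: str, path: str | None = None, line_no: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}:"
        if line_no is not None:
            loc += f"{line_no}:"
        super().__init__(f"{loc} {message}" if loc else message)
        self.path = path
        self.line_no = line_no


class ValidationError(SineupError):
    """A parsed record violates a structural invariant (e.g. CDS outside exons)."""


class ContractError(SineupError):
    """An operation was called outside its precondition (e.g. same-strand pair)."""


class NoTisError(SineupError):
    """Transcript has no CDS, so no translation initiation site can be derived."""


class ConfigError(SineupError):
    """A configuration value refers to something unknown (e.g. a repeat class)."""


class TargetError(SineupError):
    """The requested binding-domain window does not fit the target mRNA."""


class CoordError(SineupError):
    """A genomic interval falls outside the available sequence."""


class SequenceError(SineupError):
    """A nucleotide string contains characters outside the {A,C,G,T,N} alphabet."""


class GenerationError(SineupError):
    """The synthetic-data generator could not satisfy the requested geometry."""
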