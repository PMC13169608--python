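"""Exception hierarchy for splicequant."""


class SpliceQuantError(Exception):
    """Base class for all splicequant errors."""


class ConfigError(SpliceQuantError):
    """A configuration file is missing, unreadable, or lacks a required field."""


class LocusValidationError(SpliceQuantError):
    """A locus definition violates a structural invariant (ordering, contiguity)."""


class CigarParseError(SpliceQuantError):
    """A CIGAR string does not match the SAM grammar.

    Attributes
    ----------
    offset : int
        0-based character offset of the first malformed token.
    """

    def __init__(self, message: str, offset: int = 0):
        super().__init__(message)
        self.offset = offset


class AlignmentInputError(SpliceQuantError):
    """An alignment file cannot be used as required (missing index, unknown chromosome)."""


class ContractError(SpliceQuantError):
    """An operation was called on input violating its documented precondition."""
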