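"""Exception hierarchy shared across the package."""


class KmeridxError(Exception):
    """Base class for all errors raised by kmeridx."""


class AmbiguousBaseError(KmeridxError):
    """A sequence contained a character outside {A, C, G, T}."""


class LengthError(KmeridxError):
    """Sequence length does not match the expected k-mer length."""


class RangeError(KmeridxError):
    """A packed code or key is outside its valid range."""


class CapacityError(KmeridxError):
    """The hash table cannot grow any further."""


class EmptyInputError(KmeridxError):
    """An input file contained no usable records."""


class DuplicateContigNameError(KmeridxError):
    """Two contigs in the same FASTA share a name."""


class UnknownContigError(KmeridxError):
    """A coordinate query named a contig the source does not contain."""


class OutOfBoundsError(KmeridxError):
    """A coordinate interval extends past the end of its contig."""


class FormatError(KmeridxError):
    """An index file is truncated or has an unexpected magic/version."""


class ChecksumError(KmeridxError):
    """Stored checksum does not match the recomputed one."""


class ReferenceMismatchError(KmeridxError):
    """A variant's REF allele disagrees with the reference sequence."""


class MissingAFKeyError(KmeridxError):
    """A requested allele-frequency INFO key is absent from a record."""


class ParseError(KmeridxError):
    """A region string could not be parsed."""


class InvertedIntervalError(ParseError):
    """Region start is greater than its end."""


class ConfigError(KmeridxError):
    """Simulation parameters are inconsistent or infeasible."""
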