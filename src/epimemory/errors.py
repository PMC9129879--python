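"""Exception hierarchy for epimemory.

Every anticipated failure mode raises a subclass of :class:`EpimemoryError`
so callers (and the CLI) can distinguish bad input from bugs.
"""


class EpimemoryError(Exception):
    """Base class for all errors raised by this package."""


class TraceFormatError(EpimemoryError):
    """A trace file is malformed or violates a TraceSignal invariant."""


class ValidationError(EpimemoryError):
    """An in-memory object violates its type invariants."""


class LocusNotFoundError(EpimemoryError):
    """The SNP locus context does not occur in the called-base sequence."""


class AmbiguousLocusError(EpimemoryError):
    """The SNP locus context occurs more than once in the called bases."""


class DegenerateSignalError(EpimemoryError):
    """Both allele channels have zero baseline-corrected area."""


class RankDeficiencyError(EpimemoryError):
    """A fit cannot be performed because the design is rank deficient."""


class UnusableCurveError(EpimemoryError):
    """A standard curve with non-positive slope cannot be inverted."""


class UnboundedRatioError(EpimemoryError):
    """An allele fraction of exactly 0 or 1 makes the odds ratio unbounded."""


class PairingError(EpimemoryError):
    """A competition replicate is missing its start or end timepoint."""


class IdentifiabilityError(EpimemoryError):
    """Fewer timepoints than free parameters in a decay fit."""


class InsufficientReplicationError(EpimemoryError):
    """Fewer than two replicates where a dispersion estimate is required."""
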