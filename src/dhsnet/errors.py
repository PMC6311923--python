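"""Exception hierarchy shared across the package."""


class DhsnetError(Exception):
    """Base class for all package-specific errors."""


class FastaFormatError(DhsnetError):
    """Raised when a FASTA file is empty, malformed, or contains
    characters outside the {A, C, G, T, N} alphabet."""


class BedFormatError(DhsnetError):
    """Raised on malformed BED interval lines; the message carries the
    1-based line number."""


class CoordinateError(DhsnetError):
    """Raised when an interval refers to an unknown chromosome or falls
    outside chromosome bounds."""


class SequenceEncodingError(DhsnetError):
    """Raised when a sequence cannot be one-hot encoded."""


class SamplingError(DhsnetError):
    """Raised when no feasible negative placement exists for a positive."""


class ExtensionError(DhsnetError):
    """Raised when a fragment cannot be extended to its bin's target
    length on its chromosome."""


class BinAssignmentError(DhsnetError):
    """Raised when a fragment length falls outside the binned range."""


class ModelConfigError(DhsnetError):
    """Raised on inconsistent network configuration."""


class BatchError(DhsnetError):
    """Raised when a prediction batch violates the equal-length contract."""


class MetricError(DhsnetError):
    """Raised when an evaluation statistic is undefined for the input."""
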