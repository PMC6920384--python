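"""Exception hierarchy shared across sortramp modules."""


class SortrampError(Exception):
    """Base class for all sortramp-specific errors."""


class AlphabetError(SortrampError, ValueError):
    """A sequence contains characters outside the expected alphabet."""


class CapacityError(SortrampError, ValueError):
    """More distinct sequences requested than the alphabet allows."""


class ConfigurationError(SortrampError, ValueError):
    """Inconsistent or impossible configuration values."""


class ZeroDepthBinError(SortrampError, ValueError):
    """A FACS bin has zero sequencing depth where depth is required."""


class UndefinedScoreError(SortrampError, ValueError):
    """A score is requested for a variant with no read mass anywhere."""


class InsufficientDataError(SortrampError, ValueError):
    """Too few observations to compute the requested statistic."""


class PatternError(SortrampError, ValueError):
    """A motif pattern is malformed (bad IUPAC code, bad offsets...)."""


class TraceFormatError(SortrampError, ValueError):
    """A single-molecule trace violates the alternating-state contract."""


class SchemaError(SortrampError, ValueError):
    """A tabular input does not match the expected column schema."""


class GapError(SortrampError, ValueError):
    """A time series is missing required time points."""
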