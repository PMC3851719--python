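"""Exception hierarchy for pullfe."""


class PullfeError(Exception):
    """Base class for all package errors."""


class DomainError(PullfeError, ValueError):
    """A coordinate lies outside the landscape domain."""


class IntegrationError(PullfeError, RuntimeError):
    """The Langevin integration produced a non-finite state."""


class DegeneratePartitionError(PullfeError, ValueError):
    """A bound/unbound partition has an empty or zero-weight state."""


class CalibrationError(PullfeError, RuntimeError):
    """Well-depth calibration could not bracket the target free energy."""


class ShapeError(PullfeError, ValueError):
    """Input series have mismatched lengths or shapes."""


class ConventionError(PullfeError, ValueError):
    """Results with incompatible direction/temperature conventions combined."""


class FormatError(PullfeError, ValueError):
    """A COLVAR or TSV file is malformed."""


class ParameterCoverageError(PullfeError, KeyError):
    """A nearest-neighbor step is missing from the parameter table."""


class InvalidDuplexError(PullfeError, ValueError):
    """A duplex contains a non-pairable position."""


class DiagnosticsError(PullfeError, RuntimeError):
    """Too many bootstrap resamples failed for a reliable standard error."""
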