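"""Exception hierarchy.

Degeneracy (singular covariance) is an expected, recoverable condition for
individual analysis windows -- the study style is to flag and exclude such
windows, not to abort -- so it gets its own class that callers can catch.
"""


class PhiStressError(Exception):
    """Base class for all package errors."""


class SegmentLengthError(PhiStressError, ValueError):
    """A time-series segment is too short for the requested estimation."""


class DegenerateModelError(PhiStressError):
    """A covariance matrix is singular (or numerically indefinite).

    Raised when a lagged Gaussian model, or a part-restricted model under a
    partition, cannot support the information quantities (e.g. a constant
    channel, a duplicated channel, or an all-zero padded window).
    """


class NumericalError(PhiStressError):
    """An optimizer failed to converge or a quantity fell outside the
    tolerance band that separates round-off from a genuine defect."""


class ReliabilityError(PhiStressError):
    """Too many windows were missing/degenerate for a summary to be trusted."""


class ExclusivityError(PhiStressError):
    """Two main complexes overlap while exclusivity enforcement is on."""
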