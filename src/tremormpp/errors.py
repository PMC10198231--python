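"""Exception hierarchy for tremormpp."""


class TremorMPPError(Exception):
    """Base class for all package-specific errors."""


class InvalidBandError(TremorMPPError, ValueError):
    """Frequency band edges are mis-ordered or outside the spectral range."""


class CalibrationError(TremorMPPError, ValueError):
    """Generator parameters are outside their calibratable range."""


class ValidationError(TremorMPPError, ValueError):
    """A domain object violates one of its invariants."""


class InsufficientDataError(TremorMPPError, ValueError):
    """A trace is too short for the requested estimator."""


class DataError(TremorMPPError, ValueError):
    """Input samples are non-finite or otherwise unusable."""


class UndefinedStatisticError(TremorMPPError, ZeroDivisionError):
    """A ratio statistic is undefined (zero denominator power)."""


class AggregationError(TremorMPPError, ValueError):
    """Duplicate animal/epoch keys while building a results table."""


class ManifestError(TremorMPPError, ValueError):
    """Cohort manifest is inconsistent (e.g. duplicate animal ids)."""


class UnbalancedDesignError(TremorMPPError, ValueError):
    """An animal is missing one or more epochs; listwise deletion is never silent."""


class DesignRankError(TremorMPPError, ValueError):
    """The fixed-effect design is singular (too few doses/animals)."""


class LookupError_(TremorMPPError, KeyError):
    """Requested dose/epoch/drug/line is not present."""


class DegenerateSampleError(TremorMPPError, ValueError):
    """A diagnostic requires variability the sample does not have."""
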