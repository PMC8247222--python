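"""Exception and warning hierarchy shared across the package."""


class SmosError(Exception):
    """Base class for all errors raised by this package."""


class InvalidMeasurementError(SmosError, ValueError):
    """A gait measurement is negative, non-finite, or otherwise unusable."""


class MissingMetricError(SmosError, ValueError):
    """A required gait metric is absent; no partial SMoS is ever emitted."""


class InvalidWalkError(SmosError, ValueError):
    """Timed walk with non-positive distance or duration."""


class NoDataError(SmosError, ValueError):
    """An empty step time series (or similar absence of data)."""


class NormsFileError(SmosError, ValueError):
    """A norms file is malformed, has missing columns, or duplicate strata."""


class NormLookupError(SmosError, LookupError):
    """No normative entry exists for the requested age/sex stratum."""


class EmptyStratumError(SmosError, ValueError):
    """A stratum summary was requested for zero scored records."""


class InsufficientDataError(SmosError, ValueError):
    """Too few observations for the requested test (n < 2)."""


class InsufficientPairsError(SmosError, ValueError):
    """Fewer than 3 complete pairs remain after pairwise deletion."""


class UndefinedCorrelationError(SmosError, ValueError):
    """Zero variance in one of the variables; r is undefined."""


class UnsupportedSampleSizeError(SmosError, ValueError):
    """Sample size outside the supported range of the normality test."""


class CohortSchemaError(SmosError, ValueError):
    """A cohort CSV is missing required columns or is unreadable."""


class CohortSpecError(SmosError, ValueError):
    """A synthetic cohort specification is invalid or infeasible."""


class SmosWarning(UserWarning):
    """Base class for warnings issued by this package."""


class NonStandardDistanceWarning(SmosWarning):
    """Timed-walk distance is not one of the standard course lengths."""


class LowCoverageWarning(SmosWarning):
    """Fewer tracked days than the configured minimum in the step window."""
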