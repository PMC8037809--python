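"""Exception and warning hierarchy for :mod:`bbbperm`."""


class BBBPermError(Exception):
    """Base class for all package errors."""


class FormatError(BBBPermError, ValueError):
    """A file could not be parsed (bad header, non-numeric cell, unknown label)."""


class ValidationError(BBBPermError, ValueError):
    """Parsed data violates a domain invariant (range, ordering, uniqueness)."""


class ConfigurationError(BBBPermError, ValueError):
    """A required configuration value (e.g. CMC for micellar data) is missing."""


class InsufficientDataError(BBBPermError, ValueError):
    """Too few points/rows for the requested fit."""


class SingularDesignError(BBBPermError, ValueError):
    """Design matrix is rank deficient (e.g. zero variance in a predictor)."""


class NonPhysicalFitError(BBBPermError, ValueError):
    """A fitted quantity has no physical interpretation (e.g. intercept <= 0)."""


class ArchiveVersionError(BBBPermError, ValueError):
    """A model archive was written with an unsupported schema version."""


class DataQualityWarning(UserWarning):
    """Non-fatal data issue: few replicates, dropped level, tie broken, ..."""


class NonPhysicalWarning(UserWarning):
    """Fitted value outside its physical range (e.g. negative K_MA)."""
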