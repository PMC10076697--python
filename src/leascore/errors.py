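"""Exception hierarchy for leascore."""


class LeasError(Exception):
    """Base class for all leascore errors."""


class FormatError(LeasError):
    """A file does not have the expected structure (missing columns, bad header)."""


class ValidationError(LeasError):
    """Input content violates an invariant (duplicate ids, out-of-range values)."""


class UsageError(LeasError):
    """An operation was called with incompatible or unknown arguments."""


class UndefinedStatisticError(LeasError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class DegenerateDesignError(LeasError):
    """A covariate design matrix is rank deficient."""
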