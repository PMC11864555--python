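"""Exception hierarchy shared across the package.

Every error raised on a user-facing code path derives from ChumrunError so the
CLI can map failures onto its exit-code contract (2 = validation, 3 = fit).
"""


class ChumrunError(Exception):
    """Base class for all package errors."""


class OutOfWindowError(ChumrunError):
    """A date or day index falls outside the Oct 1 - Dec 31 analysis window."""


class DataQualityError(ChumrunError):
    """Input series violates a data-quality rule (gaps, negatives, schema)."""


class ValidationError(ChumrunError):
    """Input files or configuration failed validation."""


class ScenarioError(ChumrunError):
    """Synthetic-data scenario parameters are inconsistent or out of range."""


class UndefinedStatisticError(ChumrunError):
    """A statistic (MDMT, residence time) is undefined for the given input."""


class ClassificationError(ChumrunError):
    """A year could not be assigned an SST regime label."""


class InsufficientDataError(ChumrunError):
    """Too few observations to compute a baseline or fit a model."""


class DesignError(ChumrunError):
    """Model design matrix is singular (e.g. a regime with zero records)."""


class FitError(ChumrunError):
    """A model fit failed to converge or could not be computed."""


class ComparabilityError(ChumrunError):
    """Model fits being compared were not computed on identical data."""
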