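"""Exception hierarchy shared across the package."""


class RecipError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RecipError):
    """A cohort file does not match the documented column schema."""


class CohortValidationError(RecipError):
    """A patient record violates a domain invariant (negative volume, bad flag...)."""


class DegenerateBaselineError(RecipError):
    """Percent change requested against a zero baseline.

    A zero baseline volume or PSA has no defined percent change; classification
    of such patients must route through the complete-response / new-disease
    rules instead.
    """


class UndefinedStatisticError(RecipError):
    """A statistic has no defined value on the given sample.

    Raised e.g. when a concordance index has no usable pair, or when chance
    agreement is exactly 1 so Fleiss kappa has a zero denominator.
    """


class ConvergenceError(RecipError):
    """An iterative fit failed to converge (e.g. monotone Cox partial likelihood)."""
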