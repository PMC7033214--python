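"""Exception types raised across the package."""


class InvalidParameterError(ValueError):
    """A configuration or call parameter is outside its valid range."""


class InvalidInputError(ValueError):
    """A data object (solution, profile, log) violates its contract."""


class ResourceGuardError(RuntimeError):
    """An exhaustive computation was refused because the problem is too large."""


class EstimatorUndefinedError(ValueError):
    """The requested estimate is undefined on the given data (e.g. empty denominator)."""


class DegenerateFitError(ValueError):
    """A regression cannot be fit because the predictor has zero variance."""


class MissingConditionError(KeyError):
    """An aggregate requires a condition pair that is absent from the input."""
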