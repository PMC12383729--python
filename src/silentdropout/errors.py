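"""Exception hierarchy.

Every error raised on bad input derives from :class:`SilentDropoutError` so
callers can catch the package's failures without masking programming errors.
"""


class SilentDropoutError(ValueError):
    """Base class for all input/configuration errors raised by this package."""


class InvalidConfigError(SilentDropoutError):
    """A simulation or model configuration violates its invariants."""


class InvalidInputError(SilentDropoutError):
    """A data argument is outside its documented domain."""


class InsufficientDataError(SilentDropoutError):
    """An operation needs observations that the input does not contain."""


class InvalidDesignError(SilentDropoutError):
    """A two-group design has too few samples in a group."""


class DegenerateOutcomeError(SilentDropoutError):
    """Outcome vector contains a single class; the model is not identifiable."""


class SeparationError(SilentDropoutError):
    """Complete separation: logistic coefficients diverge.

    ``direction`` is +1 when the slope runs to +inf, -1 when to -inf.
    """

    def __init__(self, message: str, direction: int):
        super().__init__(message)
        self.direction = direction


class StratificationError(SilentDropoutError):
    """A class is too small to spread over the requested folds."""


class PairingError(SilentDropoutError):
    """Paired score vectors do not align on the same observations."""


class DegenerateVarianceError(SilentDropoutError):
    """A test statistic has zero variance but a nonzero effect."""


class UndefinedMetricError(SilentDropoutError):
    """A requested metric has an empty denominator class."""


class JoinError(SilentDropoutError):
    """Foreign keys fail to resolve during a table join.

    ``missing`` lists the offending identifiers.
    """

    def __init__(self, message: str, missing):
        super().__init__(message)
        self.missing = list(missing)


class NoReferenceError(SilentDropoutError):
    """No gene has all-positive counts; median-of-ratios has no reference."""


class UndefinedCorrelationError(SilentDropoutError):
    """A correlation is undefined because one vector is constant."""
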