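"""Exception hierarchy shared across the package."""


class BcicmError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BcicmError, ValueError):
    """An input violates a documented precondition (empty image, bad shape, ...)."""


class NoPairsError(InvalidInputError):
    """The image admits no pixel pair at the requested (distance, angle) offset."""


class GLCMContractError(BcicmError, ValueError):
    """A texture statistic was asked for on an unnormalized co-occurrence table."""


class DegenerateCorrelationError(BcicmError, ArithmeticError):
    """GLCM correlation is undefined: a marginal standard deviation is zero
    (e.g. a constant image)."""


class UndefinedMetricError(BcicmError, ZeroDivisionError):
    """A classification metric has a zero denominator.

    Carries the metric name in ``metric``.
    """

    def __init__(self, metric: str, message: str | None = None):
        self.metric = metric
        super().__init__(message or f"metric {metric!r} is undefined (zero denominator)")


class EmptyDatasetError(InvalidInputError):
    """An image folder or point set contains no usable samples."""


class ConfigError(BcicmError, ValueError):
    """A configuration file violates the documented key schema."""
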