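"""Error types shared across the circuit model and its analyses."""


class StriodmError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StriodmError, ValueError):
    """A parameter violates its documented domain (e.g. c <= 0, prob outside [0,1])."""


class ShapeError(StriodmError, ValueError):
    """Array arguments have incompatible shapes."""


class UndefinedStatisticError(StriodmError, ValueError):
    """A statistic is undefined for the given sample (too few points, zero variance)."""


class InsufficientDataError(StriodmError, ValueError):
    """Not enough events/observations to run the analysis."""


class DivergenceError(StriodmError, RuntimeError):
    """A simulated state exceeded the divergence guard."""

    def __init__(self, message: str, dimension=None):
        super().__init__(message)
        self.dimension = dimension
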