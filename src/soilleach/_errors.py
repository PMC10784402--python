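"""Exception hierarchy shared across the package."""


class SoilLeachError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SoilLeachError, ValueError):
    """An input violates a documented precondition."""


class InsufficientDataError(InvalidInputError):
    """Too few observations to fit the requested model."""


class FitFailureError(SoilLeachError, RuntimeError):
    """A nonlinear fit did not converge.

    Attributes
    ----------
    residual_norm : float or None
        Euclidean norm of the residuals at the last evaluated point,
        when available.
    """

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class GenerationError(SoilLeachError, RuntimeError):
    """Synthetic-data generation could not satisfy its mass balance."""


class ScenarioValidationError(SoilLeachError, ValueError):
    """A scenario configuration failed validation.

    Collects *all* violations rather than the first one.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid scenario:\n  - " + "\n  - ".join(self.errors))
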