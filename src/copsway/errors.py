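"""Exception hierarchy for the COP analysis pipeline.

Every stage raises a subclass of :class:`CopswayError` so the CLI can tag
failures with the stage that produced them.
"""


class CopswayError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CopswayError):
    """Input file does not match the declared dialect (missing/ill-typed column)."""


class SamplingRateError(CopswayError):
    """Inferred sampling rate disagrees with the declared one beyond tolerance."""


class EmptySignalError(CopswayError):
    """No valid samples remain after masking."""


class DurationError(CopswayError):
    """Recording shorter than the acclimation lead plus analysis window."""


class ParameterError(CopswayError):
    """Invalid analysis parameter (e.g. cutoff at or above Nyquist)."""


class LengthError(CopswayError):
    """Series too short for the requested computation."""


class NormalizationError(CopswayError):
    """Anthropometrics required by the normalization scheme are missing."""


class PredictorDomainError(CopswayError):
    """A model predictor is outside the equation's domain (non-finite, non-positive)."""

    def __init__(self, name: str, value, message: str | None = None):
        self.name = name
        self.value = value
        super().__init__(message or f"predictor {name!r} out of domain: {value!r}")


class MissingPredictorError(CopswayError, KeyError):
    """A required (parameter, direction) key is absent from the parameter set."""


class DegenerateOutcomeError(CopswayError):
    """Outcome vector is constant; screening/fitting undefined."""


class SeparationError(CopswayError):
    """Perfect separation: logistic likelihood unbounded."""


class ConvergenceError(CopswayError):
    """Iterative fit failed to converge."""

    def __init__(self, iterations: int, message: str | None = None):
        self.iterations = iterations
        super().__init__(message or f"fit did not converge in {iterations} iterations")
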