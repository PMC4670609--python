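"""Exception hierarchy for cardiogrowth."""


class CardioGrowthError(Exception):
    """Base class for all package errors."""


class ParameterError(CardioGrowthError, ValueError):
    """Invalid material or scenario parameter."""


class FrameError(CardioGrowthError, ValueError):
    """Fiber/sheet/normal frame is not orthonormal or not unit length."""


class InvalidGrowthStateError(CardioGrowthError, ValueError):
    """Growth tensor is singular or the growth state is inadmissible."""


class InvertedElementError(CardioGrowthError, FloatingPointError):
    """A deformation state has non-positive Jacobian (element inversion)."""


class GeometryError(CardioGrowthError, ValueError):
    """Infeasible geometry parameters or malformed mesh."""


class DiagnosticError(CardioGrowthError, ValueError):
    """A geometric diagnostic cannot be evaluated (open surface, missing tag)."""


class ConfigError(CardioGrowthError, ValueError):
    """Scenario configuration is invalid or incomplete."""


class CalibrationError(CardioGrowthError, RuntimeError):
    """Homeostatic-threshold calibration attempted on an unconverged state."""


class SolverError(CardioGrowthError, RuntimeError):
    """Newton iteration or load stepping failed."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StepRejected(CardioGrowthError, RuntimeError):
    """A trial load/Newton step produced an inadmissible state; caller should
    halve the increment."""
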