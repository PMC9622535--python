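"""Exception hierarchy shared across the pipeline stages."""


class FontanFlowError(Exception):
    """Base class for all package errors."""


class InvalidInputError(FontanFlowError, ValueError):
    """A scalar argument or parameter set violates its contract."""


class DimensionError(FontanFlowError, ValueError):
    """Field and grid shapes do not match."""


class GeometryError(FontanFlowError, ValueError):
    """Invalid, disconnected or non-watertight geometry."""


class ResolutionError(FontanFlowError, ValueError):
    """Grid spacing too coarse to resolve a limb."""


class FormatError(FontanFlowError, ValueError):
    """Unreadable or malformed file content."""


class SamplingError(FontanFlowError, ValueError):
    """Too few waveform samples for the requested harmonic content."""


class ConfigurationError(FontanFlowError, ValueError):
    """A port, key or option referenced in a run setup does not exist."""


class ConvergenceError(FontanFlowError, RuntimeError):
    """Solver failed to reach the residual tolerance.

    Carries the residual history so callers can inspect the failure.
    """

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history


class TimeStepError(FontanFlowError, ValueError):
    """Requested time step violates the CFL stability bound.

    ``suggested_dt`` is the largest stable step for the same state.
    """

    def __init__(self, message, suggested_dt=None):
        super().__init__(message)
        self.suggested_dt = suggested_dt
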