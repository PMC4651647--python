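"""Exception hierarchy used across the package."""


class HelixGeomError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HelixGeomError, ValueError):
    """Invalid model or generator parameters."""


class InputError(HelixGeomError, ValueError):
    """Malformed or inconsistent input data (wrong shapes, ragged frames, ...)."""


class DomainError(HelixGeomError, ValueError):
    """Evaluation of a fitted curve outside its parameter domain."""


class SingularGeometryError(HelixGeomError, ValueError):
    """Degenerate geometry: vanishing tangent, zero-length ruling, ...

    Carries the parameter value(s) at which the singularity occurred when known.
    """

    def __init__(self, message: str, u=None):
        super().__init__(message)
        self.u = u


class PipelineError(HelixGeomError, RuntimeError):
    """Every frame of a trajectory analysis failed; per-frame log attached."""

    def __init__(self, message: str, frame_log=None):
        super().__init__(message)
        self.frame_log = frame_log or []
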