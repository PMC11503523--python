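"""Exception hierarchy."""


class MetallospecError(Exception):
    """Base class for all package errors."""


class UsageError(MetallospecError, ValueError):
    """Invalid arguments or inconsistent inputs."""


class ModelError(MetallospecError):
    """The equilibrium model itself is ill-posed (no physical solution)."""


class ConvergenceError(MetallospecError):
    """Iterative solver failed to converge.

    Carries diagnostics: the last residual vector and the iteration count,
    so callers can report which mass balance failed.
    """

    def __init__(self, message, residuals=None, iterations=None, context=None):
        super().__init__(message)
        self.residuals = residuals
        self.iterations = iterations
        self.context = context
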