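"""Exception hierarchy shared across the package."""


class HydromeltError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(HydromeltError, ValueError):
    """Raised when an input violates a documented precondition."""


class FitFailureError(HydromeltError, RuntimeError):
    """Raised when a nonlinear fit fails to converge.

    Carries residual diagnostics so callers can log or inspect them.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoOnsetError(HydromeltError):
    """All points already above the onset threshold: no onset to locate."""


class NoMeltingError(HydromeltError):
    """No point exceeds the onset threshold: nothing has melted."""


class MissingHighTError(HydromeltError):
    """No reliable point close enough to T_fn = 1 for n_he estimation."""


class UndefinedRatioError(HydromeltError, ZeroDivisionError):
    """A heterogeneity ratio is undefined for the given inputs."""
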