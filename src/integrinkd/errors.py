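"""Exception hierarchy shared across the pipeline stages."""


class IntegrinKdError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IntegrinKdError, ValueError):
    """A configuration or model parameter violates its domain."""


class InvalidDataError(IntegrinKdError, ValueError):
    """Input data violate a structural invariant (schema, monotonicity, counts)."""


class FitFailureError(IntegrinKdError, RuntimeError):
    """A nonlinear fit did not converge; carries diagnostics.

    Attributes
    ----------
    diagnostics : dict
        Solver status, messages and the restart grid that was attempted.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
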