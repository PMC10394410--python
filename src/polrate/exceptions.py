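"""Exception hierarchy shared across the package."""


class PolrateError(Exception):
    """Base class for all package-specific errors."""


class InvalidStateError(PolrateError, ValueError):
    """A lattice/density state violates its invariants (non-finite values,
    occupancies outside [0, 1] beyond tolerance, negative rates...)."""


class ParameterError(PolrateError, ValueError):
    """A model parameter is outside its admissible domain."""


class IntegrationError(PolrateError, RuntimeError):
    """A forward integration failed or left the admissible state space."""


class ConvergenceError(PolrateError, RuntimeError):
    """An iterative computation (stationary state, Cholesky jitter ladder,
    slice-sampling bracket) did not converge within its budget.

    Attributes
    ----------
    diagnostics : object, optional
        Solver-specific payload (e.g. the residual trajectory).
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class ConfigError(PolrateError, ValueError):
    """Invalid run configuration (CLI / config file)."""
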