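"""Exception hierarchy shared across the package."""


class PlaqstabError(Exception):
    """Base class for all package-specific errors."""


class ResponseDomainError(PlaqstabError, ValueError):
    """Concentration outside the valid domain of a response function."""


class EquilibriumNotFoundError(PlaqstabError, RuntimeError):
    """No positive root of the macrophage-influx balance could be bracketed."""


class InvalidCoefficientsError(PlaqstabError, ValueError):
    """Linearized coefficients violate a precondition of an analysis step."""


class CertificateUnavailableError(PlaqstabError, RuntimeError):
    """Energy certificate cannot be constructed; names the failing criterion."""

    def __init__(self, failing: str, message: str | None = None):
        self.failing = failing
        super().__init__(message or f"certificate unavailable: {failing}")


class ConfigurationError(PlaqstabError, ValueError):
    """Invalid grid, perturbation or run configuration."""


class SolverError(PlaqstabError, RuntimeError):
    """Time integration failed; carries the integrator diagnostic."""
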