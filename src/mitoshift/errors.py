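"""Exception hierarchy shared across the package."""


class MitoshiftError(Exception):
    """Base class for all package-specific errors."""


class UndefinedReferenceError(MitoshiftError):
    """Reference (maternal) heteroplasmy is 0 or 1, so a shift is undefined."""


class SaturationError(MitoshiftError):
    """A quantity sits at its ceiling (h = 1, or every droplet positive)."""


class BoundaryHeteroplasmyError(MitoshiftError):
    """Heteroplasmy of 0 or 1 reached a transform that requires an interior value."""


class InsufficientDataError(MitoshiftError):
    """Too few usable records for the requested analysis."""


class DegenerateInputError(MitoshiftError):
    """Input with no variation where variation is required (e.g. constant covariate)."""


class ConvergenceError(MitoshiftError):
    """Series or iteration failed to reach the requested accuracy."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class SchemaError(MitoshiftError):
    """Tabular input failed validation; carries per-row error listing."""

    def __init__(self, message: str, errors: list[str] | None = None):
        super().__init__(message)
        self.errors = errors or []
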