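"""Exception hierarchy for the flimfret pipeline.

Every stage raises a subclass of :class:`FlimFretError`, so callers can catch
pipeline failures without masking programming errors.
"""


class FlimFretError(Exception):
    """Base class for all flimfret errors."""


class ParameterError(FlimFretError, ValueError):
    """An argument or configuration field is invalid; the message names it."""


class SchemaError(FlimFretError, ValueError):
    """A table does not conform to its declared schema."""


class ConfigurationError(FlimFretError, ValueError):
    """A run configuration is inconsistent or incomplete."""


class InsufficientPhotonsError(FlimFretError):
    """A decay histogram has too few photons for a reliable lifetime fit."""


class DegenerateDecayError(FlimFretError):
    """All photons fall in a single time bin; no decay to fit."""


class ReferenceUnavailableError(FlimFretError):
    """Too few donor-only regions to estimate the unquenched lifetime."""


class FitFailureError(FlimFretError):
    """Nonlinear fit failed to converge; carries multistart diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientDataError(FlimFretError):
    """Fewer data points than the fit requires."""


class FlatResponseError(FlimFretError):
    """Dose-response data show no concentration dependence; IC50 unidentifiable."""


class UndefinedResistanceError(FlimFretError):
    """Reference signal indistinguishable from collision background."""
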