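"""Exception hierarchy for nirsoil."""


class NirsoilError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NirsoilError):
    """Invalid parameter or profile configuration."""


class DataError(NirsoilError):
    """Input data violates a precondition (e.g. non-positive reflectance)."""


class DegenerateDistanceError(NirsoilError):
    """Both spectral and concentration distances are identically zero."""


class DimensionalityError(NirsoilError):
    """More regressors than samples for an OLS fit."""


class FitError(NirsoilError):
    """Model fitting failed (degenerate design matrix)."""


class SelectionError(NirsoilError):
    """Variable selection has no admissible candidates."""


class UndefinedCorrelationError(NirsoilError):
    """Correlation requested for a constant vector."""


class ZeroSDError(NirsoilError):
    """Standard deviation of reference values is zero."""


class InfiniteRPDError(NirsoilError):
    """RPD requested with a zero prediction error."""
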