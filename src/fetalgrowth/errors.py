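"""Exception hierarchy.

Every error raised by the package derives from :class:`FetalGrowthError` and
carries a stable machine-readable ``code`` used by the command-line surface.
"""


class FetalGrowthError(Exception):
    code = "error"


class InvalidParameterError(FetalGrowthError):
    """A numeric argument is outside its admissible range (e.g. tau not in (0,1))."""
    code = "invalid-parameter"


class SingularDesignError(FetalGrowthError):
    """Design matrix is rank deficient; coefficients are not identifiable."""
    code = "singular-design"


class ConvergenceError(FetalGrowthError):
    """The LP solver did not reach an optimal vertex."""
    code = "convergence"

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateSparsityError(FetalGrowthError):
    """Sparsity difference quotient non-positive at the requested bandwidth."""
    code = "degenerate-sparsity"


class SingularContrastError(FetalGrowthError):
    code = "singular-contrast"


class InvalidMeasurementError(FetalGrowthError):
    code = "invalid-measurement"


class MissingMeasurementError(FetalGrowthError):
    code = "missing-measurement"


class MissingCovariateError(FetalGrowthError):
    code = "missing-covariate"


class DegenerateSpreadError(FetalGrowthError):
    """Quartiles coincide; the Bowley coefficient is undefined."""
    code = "degenerate-spread"


class IncompatibleChartsError(FetalGrowthError):
    code = "incompatible-charts"


class UnknownStratumError(FetalGrowthError):
    code = "unknown-stratum"


class UnknownParameterError(FetalGrowthError):
    code = "unknown-parameter"


class OffGridError(FetalGrowthError):
    """Exact-cell lookup requested off the printed week/percentile grid."""
    code = "off-grid"


class GARangeError(FetalGrowthError):
    code = "ga-range"


class ChartIntegrityError(FetalGrowthError):
    """Bundled chart file does not match its recorded checksum."""
    code = "chart-integrity"


class SchemaError(FetalGrowthError):
    code = "schema"


class IntegrityError(FetalGrowthError):
    code = "integrity"


class ConfigError(FetalGrowthError):
    code = "config"
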