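"""Exception hierarchy used across the package."""


class MRMediateError(Exception):
    """Base class for all package errors."""


class FormatError(MRMediateError):
    """A summary-statistics file does not conform to the declared dialect."""


class InputError(MRMediateError):
    """Inputs are syntactically valid but unusable (empty table, bad region)."""


class InsufficientInstrumentsError(MRMediateError):
    """Too few instruments survive selection/harmonization for an estimator."""


class EstimationError(MRMediateError):
    """An estimator failed to converge; diagnostics attached when available."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConfigError(MRMediateError):
    """A configuration value is out of its valid range."""
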