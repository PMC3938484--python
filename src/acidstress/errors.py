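"""Exception hierarchy shared across the package."""


class AcidStressError(Exception):
    """Base class for package errors."""


class InvalidInputError(AcidStressError, ValueError):
    """Raised when an input violates a documented precondition."""


class CalibrationError(AcidStressError):
    """Raised when a calibration fit cannot be produced or fails quality checks."""


class SolverError(AcidStressError):
    """Raised when a numerical solver fails to reach its target."""


class ConfigError(AcidStressError):
    """Raised for pipeline configuration problems; names the offending stage."""
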