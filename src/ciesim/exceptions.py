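"""Exception types raised across the package."""


class CiesimError(Exception):
    """Base class for package errors."""


class InvalidParameterError(CiesimError, ValueError):
    """A configuration or argument value is outside its valid range."""


class UnsupportedFamilyError(CiesimError, ValueError):
    """Outcome family is not one of binary / continuous / survival."""


class DegenerateOutcomeError(CiesimError, ValueError):
    """Binary outcome with a single class; no model can be fit."""


class DegenerateInputError(CiesimError, ValueError):
    """Zero-variance input where variation is required (e.g. screening)."""


class UndefinedCIEError(CiesimError, ArithmeticError):
    """Change-in-estimate undefined because the unadjusted effect is zero."""


class MissingParameterError(CiesimError, ValueError):
    """A required parameter (cutoff, baseline risk, ...) was not supplied."""


class CalibrationFailureError(CiesimError, RuntimeError):
    """All calibration replicates were degenerate; no cutoff can be formed."""


class InvalidStructureError(CiesimError, ValueError):
    """Requested correlation structure is not positive definite."""


class ConfigError(CiesimError, ValueError):
    """Configuration file failed schema validation."""
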