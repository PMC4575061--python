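"""Exception hierarchy for the model."""


class GlaucomaCEAError(Exception):
    """Base class for package errors."""


class ValidationError(GlaucomaCEAError, ValueError):
    """A domain object violates one of its invariants."""


class ConfigurationError(GlaucomaCEAError, ValueError):
    """A model configuration is incomplete or inconsistent."""


class CalibrationError(GlaucomaCEAError, RuntimeError):
    """Calibration failed to converge or left an unacceptable residual."""
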