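"""Exception hierarchy for the package."""


class StrokeCEAError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(StrokeCEAError, ValueError):
    """A parameter value violates its stated precondition."""


class ModelConstructionError(StrokeCEAError, ValueError):
    """A transition schedule or model input cannot be built consistently."""


class CalibrationError(StrokeCEAError, RuntimeError):
    """Calibration failed to reach the required objective value.

    Carries the best parameters found so the caller can inspect them.
    """

    def __init__(self, message, result=None):
        super().__init__(message)
        self.result = result


class ConfigError(StrokeCEAError, ValueError):
    """Configuration file failed schema validation."""
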