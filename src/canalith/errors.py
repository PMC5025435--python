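"""Exception hierarchy for the canalith package."""


class CanalithError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CanalithError, ValueError):
    """A scalar parameter violates its physical or contractual bounds."""


class PairingError(CanalithError, ValueError):
    """Two material specs that should be related by the geometric factor are not."""


class ConfigError(CanalithError, ValueError):
    """A configuration file violates the documented schema."""


class IntegrationError(CanalithError, RuntimeError):
    """The trajectory integrator failed to converge."""


class CalibrationError(CanalithError, RuntimeError):
    """Drag-factor calibration could not bracket or reach the target."""
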