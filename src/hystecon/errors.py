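"""Exception hierarchy shared across the package."""


class HysteconError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(HysteconError, ValueError):
    """Invalid numeric parameter (rate outside [0, 1], negative sd, bad bounds...)."""


class ConfigurationError(HysteconError, ValueError):
    """A configuration is structurally valid but semantically unusable
    (e.g. a literature-sourced branch probability without an override)."""


class CalibrationError(HysteconError, ValueError):
    """Fee-schedule calibration cannot identify its parameters or misses tolerance."""


class DegenerateTestError(HysteconError, ValueError):
    """A statistical test was requested on data it cannot discriminate
    (e.g. a constant variable)."""


class TreeValidationError(HysteconError, ValueError):
    """A decision tree violates a structural invariant; the message names the node."""


class StageError(HysteconError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
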