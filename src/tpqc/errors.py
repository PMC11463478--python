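"""Exception hierarchy shared by all analyses."""


class TpqcError(Exception):
    """Base class for all tpqc errors."""


class InvalidParameterError(TpqcError, ValueError):
    """A parameter violates a precondition (non-positive length, bad range, ...)."""


class DegenerateDataError(TpqcError):
    """Input data carry no usable signal (constant sweep, flat image, ...)."""


class FitFailureError(TpqcError):
    """Nonlinear least squares did not converge after multi-start."""


class DetectionFailureError(TpqcError):
    """Feature detection found too few structures to proceed."""


class NoBeadsError(DetectionFailureError):
    """No usable beads were detected or extracted from a volume."""


class MeasurementFailureError(TpqcError):
    """A profile measurement could not be made (flat profile, boundary peak)."""


class CapacityError(TpqcError):
    """A synthetic volume cannot host the requested configuration."""


class ConfigError(TpqcError):
    """The QC configuration file is unreadable or malformed."""
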