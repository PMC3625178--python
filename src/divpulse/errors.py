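"""Exception hierarchy shared across the pipeline stages."""


class DivPulseError(Exception):
    """Base class for all package errors."""


class AlignmentError(DivPulseError):
    """Malformed alignment: unequal lengths, bad alphabet, duplicate ids."""


class MaskError(DivPulseError):
    """Column mask refers to columns outside the alignment."""


class JoinError(DivPulseError):
    """Concatenation impossible (e.g. empty taxon intersection)."""


class DistanceError(DivPulseError):
    """Pairwise distance undefined or uncomputable."""


class TreeError(DivPulseError):
    """Tree construction or shape violation (e.g. non-ultrametric input)."""


class RootingError(TreeError):
    """Outgroup rooting failed (non-monophyletic outgroup)."""


class BandwidthError(DivPulseError):
    """Automatic KDE bandwidth degenerate; an explicit h is required."""


class CalibrationError(DivPulseError):
    """Distance-to-time calibration misconfigured."""


class MappingError(DivPulseError):
    """Node-to-event mapping impossible (e.g. empty event set)."""


class FitError(DivPulseError):
    """Birth-death maximum-likelihood fit did not converge."""


class FeasibilityError(DivPulseError):
    """Simulation rejected too many times (persistent extinction)."""


class GridMismatchError(DivPulseError):
    """Density curves do not share a common grid."""


class ConfigError(DivPulseError):
    """Invalid analysis configuration."""
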