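"""Exception hierarchy for the vesselflow pipeline.

Every stage raises a subclass of :class:`VesselFlowError`, so callers can
trap pipeline failures with a single except clause while still telling
stages apart.
"""


class VesselFlowError(Exception):
    """Base class for all vesselflow errors."""


class FormatError(VesselFlowError):
    """Unreadable or unsupported input container / pixel layout."""


class InputError(VesselFlowError):
    """Input violates a precondition (too few frames, bad interval, ...)."""


class BoundsError(VesselFlowError):
    """A window, ROI or coordinate lies outside the frame."""


class UndefinedCorrelationError(VesselFlowError):
    """Correlation requested on a zero-variance (uniform) window."""


class NoRestIntervalError(VesselFlowError):
    """No candidate frame window is free of undefined correlation pairs."""


class ThresholdError(VesselFlowError):
    """Automatic threshold selection failed (degenerate histogram)."""


class EstimationError(VesselFlowError):
    """Orientation estimation failed (too few pixels or no Hough peak)."""


class MeshError(VesselFlowError):
    """Lumen too narrow to place the interrogation-window mesh."""


class MatchError(VesselFlowError):
    """Cross-correlation matching impossible (zero-variance template...)."""


class FitError(VesselFlowError):
    """Velocity-profile fit failed or produced an inadmissible optimum."""


class ConfigError(VesselFlowError):
    """Analysis configuration failed validation."""
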