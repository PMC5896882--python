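"""Exception types raised across the pipeline."""


class EchospaceError(Exception):
    """Base class for all package-specific errors."""


class MissingMarker(EchospaceError):
    """A marker required for pose reconstruction is absent or invalid."""


class DegenerateMarkers(EchospaceError):
    """Marker triad is collinear (or coincident); no plane is defined."""


class ZeroRange(EchospaceError):
    """Target coincides with the egocentric origin; direction undefined."""


class PropagationError(EchospaceError):
    """Sound-propagation delay compensation failed to converge or the
    trajectory does not cover the required time."""


class InvalidErrorModel(EchospaceError):
    """Marker error radius must satisfy 0 < r < L."""


class InsideObject(EchospaceError):
    """Observer position lies inside a scene object."""


class InsufficientSpikes(EchospaceError):
    """Too few in-window spikes to build a latency profile."""


class SamplingError(EchospaceError):
    """Sampling rate too low for the requested band."""


class FitError(EchospaceError):
    """Gaussian fit impossible (too few included bins) or did not converge."""


class ConfigError(EchospaceError):
    """Invalid configuration (e.g. infeasible flight parameters)."""
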