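"""Exception hierarchy."""


class BpBreatheError(Exception):
    """Base class for all package errors."""


class FormatError(BpBreatheError):
    """File content does not conform to the expected format."""


class ConsistencyError(BpBreatheError):
    """Inputs that must agree (atom counts, selections, shapes) do not."""


class SelectionError(BpBreatheError):
    """A required atom or group is missing from a selection."""


class GeometryError(BpBreatheError):
    """Degenerate geometry (coincident/collinear points, r = 0, < 3 atoms)."""


class StatisticsError(BpBreatheError):
    """Not enough data for the requested statistic."""


class ConfigurationError(BpBreatheError):
    """Invalid scheme, missing parameters, or malformed configuration."""


class InstabilityError(BpBreatheError):
    """Numerical blow-up of a dynamics run."""


class NoPathError(BpBreatheError):
    """Start and end lie in disconnected visited regions of a grid."""
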