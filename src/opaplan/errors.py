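"""Exception hierarchy.

Geometry/feasibility errors are kept distinct from I/O errors so the CLI can
map them to different exit codes.
"""


class OpaplanError(Exception):
    """Base class for all package errors."""


class GeometryError(OpaplanError):
    """A structure specification is geometrically impossible."""


class InfeasibleGeometryError(OpaplanError):
    """The arc-angle equation has no solution for these inputs."""


class MeasurementError(OpaplanError):
    """A required structure mask is empty or unusable for measurement."""


class MachineLimitError(OpaplanError):
    """An arc would traverse the gantry's forbidden 180/-180 degree meridian."""


class DomainError(OpaplanError):
    """An argument is outside the operation's documented domain."""


class MissingMetricError(OpaplanError):
    """A constraint row references a metric that was not supplied."""


class RasterFormatError(OpaplanError):
    """A raster file or its sidecar is malformed or inconsistent."""
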