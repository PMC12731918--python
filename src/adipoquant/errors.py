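"""Exception hierarchy shared across the package."""


class AdipoQuantError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(AdipoQuantError):
    """Two grids that must share dims/spacing do not."""


class InvalidAnnotationError(AdipoQuantError):
    """A contour or ROI set violates the annotation contract."""


class OutOfBoundsError(AdipoQuantError):
    """A contour vertex lies outside the target grid."""


class EmptyRegionError(AdipoQuantError):
    """A statistics region contained no pixels."""


class InsufficientDataError(AdipoQuantError):
    """Too few paired observations for the requested statistic."""


class ConfigError(AdipoQuantError):
    """Invalid configuration value."""
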