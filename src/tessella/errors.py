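"""Exception hierarchy.

Every failure mode of the pipeline maps onto one of these so that callers
(and the CLI) can distinguish bad inputs from bad geometry from degenerate
statistics.
"""


class TessellaError(Exception):
    """Base class for all package errors."""


class ImageReadError(TessellaError):
    """File missing, truncated, or not decodable as a raster."""


class UnsupportedDepthError(TessellaError):
    """Raster is not 8-bit per channel (e.g. 16-bit TIFF, float)."""


class GeometryError(TessellaError):
    """ROI falls outside the image, or landmarks are invalid."""


class EmptyROIError(TessellaError):
    """No pixels inside the analysis region."""


class UndefinedIndexError(TessellaError):
    """Tessellation index undefined (zero mean red / black region)."""


class NoConsensusError(TessellaError):
    """All three raters disagree; no majority grade exists."""


class DegeneratePairError(TessellaError):
    """All pooled values identical in a pairwise rank test (zero variance)."""


class UndefinedStatisticError(TessellaError):
    """Statistic undefined: constant vector, P_e = 1, zero total variance."""


class ConfigError(TessellaError):
    """Invalid simulation or run configuration."""
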