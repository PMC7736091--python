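"""Exception hierarchy for hipmorph.

All package-raised errors derive from :class:`HipmorphError` so callers can
catch domain failures without swallowing programming errors.
"""


class HipmorphError(Exception):
    """Base class for all hipmorph domain errors."""


class SchemaError(HipmorphError):
    """An annotation or measurement file violates the documented schema."""


class DegenerateGeometryError(HipmorphError):
    """A geometric primitive received degenerate input.

    Examples: collinear points passed to a circumcircle, coincident
    teardrops, a zero vector in an angle computation.
    """


class LandmarkExtractionError(HipmorphError):
    """A landmark could not be located on the traced contours."""


class PhantomConstructionError(HipmorphError):
    """A phantom specification admits no valid hip geometry."""


class UndefinedMetricError(HipmorphError):
    """An agreement metric has a zero denominator for the given table."""


class ParameterError(HipmorphError):
    """A numeric parameter is outside its valid domain (non-finite angle,
    non-positive-semidefinite covariance, too-small cohort, ...)."""
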