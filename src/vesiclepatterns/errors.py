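"""Exception hierarchy for vesiclepatterns.

All package errors derive from :class:`VesiclePatternsError` so callers can
catch everything with one clause; input-validation failures additionally
derive from :class:`ValueError` to behave like ordinary Python argument
errors.
"""


class VesiclePatternsError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VesiclePatternsError, ValueError):
    """An argument violated a documented precondition."""


class GeometricInconsistencyError(VesiclePatternsError):
    """Inputs describe an impossible shape (e.g. area below the isoperimetric minimum)."""


class NoSolutionError(VesiclePatternsError):
    """A root-finding problem has no solution in the admissible bracket."""


class PackingInfeasibleError(VesiclePatternsError):
    """The requested number/size of spherical caps cannot be packed."""


class GenerationFailureError(VesiclePatternsError):
    """A stochastic generator exhausted its retry budget."""


class BeltOverflowError(VesiclePatternsError):
    """More plates were requested than fit in a single equatorial belt."""


class InsufficientPointsError(VesiclePatternsError):
    """Too few points in view for the requested measurement."""


class DegenerateGeometryError(VesiclePatternsError):
    """Points are collinear or otherwise unsuitable for triangulation."""


class DetectionFailureError(VesiclePatternsError):
    """No vesicle disk could be located in an image."""


class InsufficientClassError(VesiclePatternsError):
    """A state-space summary requires a pattern class that is absent."""


class SchemaError(VesiclePatternsError):
    """A records file does not conform to the expected column schema."""
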