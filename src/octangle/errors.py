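"""Exception hierarchy for the octangle pipeline.

Every stage raises a subclass of :class:`OctangleError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class OctangleError(Exception):
    """Base class for all octangle errors."""


class CalibrationError(OctangleError):
    """No valid physical scale (μm/pixel) could be established."""


class FormatError(OctangleError):
    """Input file bytes inconsistent with the declared format."""


class GeometryError(OctangleError):
    """A phantom specification describes impossible or out-of-bounds geometry."""


class SegmentationError(OctangleError):
    """The tissue/chamber structure expected by the pipeline was not found."""


class AnchoringError(OctangleError):
    """A landmark (scleral spur, apex) could not be localized."""


class MetricError(OctangleError):
    """An angle metric could not be computed on the given contours."""


class EvaluationError(OctangleError):
    """Classification / ROC evaluation is ill-posed for the given input."""


class ConfigurationError(OctangleError):
    """Missing or inconsistent user configuration (thresholds, methods)."""
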