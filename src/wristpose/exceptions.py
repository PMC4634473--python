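"""Exception hierarchy for wristpose.

All errors derive from :class:`WristposeError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
kinds of contract violations the pipeline distinguishes.
"""


class WristposeError(Exception):
    """Base class for all wristpose errors."""


class SchemaError(WristposeError):
    """A required column or feature is missing from an input table."""


class FormatError(WristposeError):
    """Input data violate a structural requirement (e.g. non-monotone time)."""


class ParameterError(WristposeError, ValueError):
    """A parameter is out of its admissible range."""


class ShapeError(WristposeError, ValueError):
    """Array arguments have inconsistent lengths or dimensions."""


class AnnotationError(WristposeError):
    """An annotation interval is malformed (end <= start, out of span...)."""


class WindowTooShortError(WristposeError, ValueError):
    """A window has too few samples for the requested statistic."""


class TrainingError(WristposeError):
    """Model training is impossible (e.g. a single class in the labels)."""


class EvaluationError(WristposeError):
    """An evaluation quantity is undefined on the given inputs."""


class OrderingError(WristposeError):
    """A time-ordered event sequence is out of order."""
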