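"""Exception hierarchy for the measurement pipeline.

Every error raised by this package derives from :class:`VegSizeError`, so
callers can distinguish pipeline failures from programming errors.  I/O,
schema and computation failures are separate branches because the CLI maps
them to distinct exit codes.
"""


class VegSizeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VegSizeError, ValueError):
    """A numeric argument violates a precondition (non-finite, negative...)."""


class InvalidDepthError(InvalidInputError):
    """A depth value is zero/negative where a positive distance is required."""


class DegenerateGeometryError(InvalidInputError):
    """The projected extent is too large for the radius-corrected model
    (sensor distance >= 2f: the similar-triangle construction breaks down)."""


class IncompleteDetectionError(VegSizeError):
    """A keypoint required for measurement is missing or not visible."""


class BehindCameraError(InvalidInputError):
    """A 3D point has non-positive Z and cannot be projected."""


class BoundsError(VegSizeError, IndexError):
    """A pixel coordinate falls outside the image."""


class InvalidMagnificationError(InvalidInputError):
    """Zoom magnification below 1 requested."""


class DetectorError(VegSizeError):
    """The plugged-in detector raised; carries the magnification at failure."""

    def __init__(self, magnification: float, cause: BaseException):
        self.magnification = magnification
        self.cause = cause
        super().__init__(
            f"detector failed at magnification M={magnification:g}: {cause!r}"
        )


class SegmentationFailureError(VegSizeError):
    """No foreground found by the colour-threshold segmenter."""


class UndefinedMetricError(VegSizeError):
    """A metric was requested over an empty trial list."""


class InvalidTruthError(InvalidInputError):
    """A ground-truth value is non-positive where MAPE needs a divisor."""


class SchemaError(VegSizeError):
    """An annotation file violates the six-keypoint COCO dialect."""

    def __init__(self, message: str, record_id=None):
        self.record_id = record_id
        if record_id is not None:
            message = f"record {record_id}: {message}"
        super().__init__(message)


class RenderError(VegSizeError):
    """A synthetic scene cannot be rendered (e.g. object behind camera)."""
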