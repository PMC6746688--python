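"""Exception and warning types shared across the package."""


class MammometryError(Exception):
    """Base class for all package-specific errors."""


class DegenerateCalibrationError(MammometryError):
    """Calibration segment endpoints coincide (zero pixel length)."""


class InvalidParameterError(MammometryError, ValueError):
    """A numeric argument violates its documented domain."""


class FrameMismatchError(MammometryError):
    """Points from different photo frames combined without a transform."""


class DegenerateMidlineError(MammometryError):
    """Midline endpoints coincide; no axis can be defined."""


class MissingLandmarkError(MammometryError, KeyError):
    """A landmark required for the requested computation is absent."""


class AnnotationSchemaError(MammometryError, ValueError):
    """An annotation file violates the published schema."""


class IncompleteDesignError(MammometryError):
    """Repeated-measures design has missing cells or too few levels."""


class DegenerateDataError(MammometryError):
    """Data carry no variance (or too few records) for the statistic."""


class MissingReferenceError(MammometryError):
    """A direct-measurement reference value required for accuracy is absent."""


class CalibrationInconsistencyWarning(UserWarning):
    """Two bound photos disagree on the pixel scale beyond tolerance.

    Non-fatal: the subject-to-camera distance may legitimately differ
    slightly between the relaxed and lifted photographs.
    """
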