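"""Coordinate-level primitives for calibrated photo measurements.

All inputs are continuous pixel coordinates with the image convention:
origin at the top-left corner, x increasing rightward, y increasing
downward.  Physical lengths are obtained through a :class:`Scale` derived
from an in-frame reference segment of known length.

Level ("height along the trunk") computations project landmarks
orthogonally onto the midline axis rather than along the image x-axis, so
that every centimetre-valued output is invariant under camera roll and
in-plane translation of the photograph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

from .errors import (
    CalibrationInconsistencyWarning,
    DegenerateCalibrationError,
    DegenerateMidlineError,
    FrameMismatchError,
    InvalidParameterError,
)

__all__ = [
    "PixelPoint",
    "CalibrationSegment",
    "Scale",
    "Midline",
    "SimilarityTransform",
    "compute_scale",
    "distance_px",
    "distance_cm",
    "level_of",
    "level_difference_cm",
    "midline_distance_cm",
    "bind_photos",
    "apply_transform",
]


@dataclass(frozen=True)
class PixelPoint:
    """A continuous sub-pixel coordinate in one photo frame.

    ``photo_id`` identifies the frame the point lives in; ``None`` means
    "unspecified" and is compatible with any frame.
    """

    x: float
    y: float
    photo_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidParameterError(f"non-finite pixel coordinate ({self.x}, {self.y})")

    def same_frame(self, other: "PixelPoint") -> bool:
        if self.photo_id is None or other.photo_id is None:
            return True
        return self.photo_id == other.photo_id


def _check_frames(*points: PixelPoint) -> None:
    ids = {p.photo_id for p in points if p.photo_id is not None}
    if len(ids) > 1:
        raise FrameMismatchError(
            f"points span photo frames {sorted(ids)}; map them into one frame first"
        )


@dataclass(frozen=True)
class CalibrationSegment:
    """The in-frame reference segment of known physical length (default 2 cm)."""

    endpoint_a: PixelPoint
    endpoint_b: PixelPoint
    known_length_cm: float = 2.0

    def __post_init__(self) -> None:
        _check_frames(self.endpoint_a, self.endpoint_b)
        if not math.isfinite(self.known_length_cm) or self.known_length_cm <= 0:
            raise InvalidParameterError(
                f"known_length_cm must be positive and finite, got {self.known_length_cm}"
            )
        if self.endpoint_a.x == self.endpoint_b.x and self.endpoint_a.y == self.endpoint_b.y:
            raise DegenerateCalibrationError("calibration endpoints coincide")


@dataclass(frozen=True)
class Scale:
    """Pixel density of a photo frame in pixels per centimetre."""

    pixels_per_cm: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pixels_per_cm) or self.pixels_per_cm <= 0:
            raise InvalidParameterError(
                f"pixels_per_cm must be positive and finite, got {self.pixels_per_cm}"
            )

    def to_cm(self, pixels: float) -> float:
        return pixels / self.pixels_per_cm


@dataclass(frozen=True)
class Midline:
    """The trunk's medial axis, oriented superior (sternal notch) to inferior (umbilicus).

    Treated as an oriented axis for level computations and as an infinite
    line for perpendicular distances.
    """

    superior: PixelPoint
    inferior: PixelPoint

    def __post_init__(self) -> None:
        _check_frames(self.superior, self.inferior)
        if self.superior.x == self.inferior.x and self.superior.y == self.inferior.y:
            raise DegenerateMidlineError("midline endpoints coincide")

    @property
    def axis(self) -> Tuple[float, float]:
        """Unit vector pointing from the superior to the inferior endpoint."""
        dx = self.inferior.x - self.superior.x
        dy = self.inferior.y - self.superior.y
        norm = math.hypot(dx, dy)
        return (dx / norm, dy / norm)

    @property
    def origin(self) -> PixelPoint:
        return self.superior

    @property
    def photo_id(self) -> Optional[str]:
        return self.superior.photo_id if self.superior.photo_id is not None else self.inferior.photo_id


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation + isotropic scale + translation between two photo frames."""

    rotation_rad: float
    scale_factor: float
    translation: Tuple[float, float]
    source_photo_id: Optional[str] = None
    target_photo_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.scale_factor) or self.scale_factor <= 0:
            raise InvalidParameterError(f"scale factor must be positive, got {self.scale_factor}")

    def inverse(self) -> "SimilarityTransform":
        c, s = math.cos(-self.rotation_rad), math.sin(-self.rotation_rad)
        inv_scale = 1.0 / self.scale_factor
        tx, ty = self.translation
        # p = (T(q) - t) rotated back and unscaled
        itx = -inv_scale * (c * tx - s * ty)
        ity = -inv_scale * (s * tx + c * ty)
        return SimilarityTransform(
            rotation_rad=-self.rotation_rad,
            scale_factor=inv_scale,
            translation=(itx, ity),
            source_photo_id=self.target_photo_id,
            target_photo_id=self.source_photo_id,
        )


def compute_scale(calibration: CalibrationSegment) -> Scale:
    """Derive the frame's pixel density from the reference segment.

    ``pixels_per_cm`` is the Euclidean pixel length of the segment divided
    by its known physical length.
    """
    px = math.hypot(
        calibration.endpoint_b.x - calibration.endpoint_a.x,
        calibration.endpoint_b.y - calibration.endpoint_a.y,
    )
    return Scale(pixels_per_cm=px / calibration.known_length_cm)


def distance_px(p: PixelPoint, q: PixelPoint) -> float:
    """Euclidean distance in pixels; requires a common frame."""
    _check_frames(p, q)
    return math.hypot(q.x - p.x, q.y - p.y)


def distance_cm(p: PixelPoint, q: PixelPoint, scale: Scale) -> float:
    """Euclidean distance between two landmarks in centimetres."""
    return scale.to_cm(distance_px(p, q))


def level_of(p: PixelPoint, midline: Midline) -> float:
    """Scalar projection of ``p`` onto the midline axis, in pixels.

    Zero at the superior endpoint, increasing toward the inferior
    (umbilicus) end.  This is the orthogonal projection onto the axis, so
    the value is independent of camera roll.
    """
    _check_frames(p, midline.superior, midline.inferior)
    ax, ay = midline.axis
    return (p.x - midline.superior.x) * ax + (p.y - midline.superior.y) * ay


def level_difference_cm(
    p_right: PixelPoint, p_left: PixelPoint, midline: Midline, scale: Scale
) -> Tuple[float, float]:
    """Level difference of a right/left landmark pair along the midline.

    Returns ``(signed_cm, magnitude_cm)``.  The signed value is
    right-minus-left: positive means the right-side landmark sits more
    inferior.  Clinical panels report the magnitude.
    """
    signed = scale.to_cm(level_of(p_right, midline) - level_of(p_left, midline))
    return signed, abs(signed)


def midline_distance_cm(p: PixelPoint, midline: Midline, scale: Scale) -> float:
    """Perpendicular distance from a landmark to the (infinite) midline, in cm."""
    _check_frames(p, midline.superior, midline.inferior)
    ax, ay = midline.axis
    vx = p.x - midline.superior.x
    vy = p.y - midline.superior.y
    return scale.to_cm(abs(ax * vy - ay * vx))


def project_onto_midline(p: PixelPoint, midline: Midline) -> PixelPoint:
    """Foot of the orthogonal projection of ``p`` onto the midline."""
    t = level_of(p, midline)
    ax, ay = midline.axis
    return PixelPoint(
        x=midline.superior.x + t * ax,
        y=midline.superior.y + t * ay,
        photo_id=p.photo_id if p.photo_id is not None else midline.photo_id,
    )


def bind_photos(
    midline_primary: Midline,
    midline_secondary: Midline,
    *,
    calibration_primary: Optional[CalibrationSegment] = None,
    calibration_secondary: Optional[CalibrationSegment] = None,
    scale_tolerance: float = 0.05,
) -> SimilarityTransform:
    """Solve the similarity transform mapping the secondary frame onto the primary.

    The two marked midline endpoints must correspond anatomically (same
    body points in both photos); two point correspondences determine the
    2-D similarity uniquely.  If both photos carry their own calibration
    segment, the transform's scale factor is cross-checked against the
    ratio of the two calibrated pixel densities and a
    :class:`~mammometry.errors.CalibrationInconsistencyWarning` is emitted
    when they disagree by more than ``scale_tolerance`` (relative).
    """
    # Complex-number form: T(z) = a z + b with two equations, two unknowns.
    s1 = complex(midline_secondary.superior.x, midline_secondary.superior.y)
    s2 = complex(midline_secondary.inferior.x, midline_secondary.inferior.y)
    p1 = complex(midline_primary.superior.x, midline_primary.superior.y)
    p2 = complex(midline_primary.inferior.x, midline_primary.inferior.y)
    a = (p1 - p2) / (s1 - s2)
    b = p1 - a * s1
    transform = SimilarityTransform(
        rotation_rad=math.atan2(a.imag, a.real),
        scale_factor=abs(a),
        translation=(b.real, b.imag),
        source_photo_id=midline_secondary.photo_id,
        target_photo_id=midline_primary.photo_id,
    )
    if calibration_primary is not None and calibration_secondary is not None:
        implied = (
            compute_scale(calibration_primary).pixels_per_cm
            / compute_scale(calibration_secondary).pixels_per_cm
        )
        if abs(transform.scale_factor - implied) > scale_tolerance * implied:
            warnings.warn(
                "two-photo binding scale factor "
                f"{transform.scale_factor:.4f} disagrees with the calibrated "
                f"pixel-density ratio {implied:.4f} by more than "
                f"{scale_tolerance:.0%}",
                CalibrationInconsistencyWarning,
                stacklevel=2,
            )
    return transform


def apply_transform(t: SimilarityTransform, p: PixelPoint) -> PixelPoint:
    """Express a source-frame point in the target frame."""
    if (
        p.photo_id is not None
        and t.source_photo_id is not None
        and p.photo_id != t.source_photo_id
    ):
        raise FrameMismatchError(
            f"point lives in frame {p.photo_id!r}, transform expects {t.source_photo_id!r}"
        )
    c, s = math.cos(t.rotation_rad), math.sin(t.rotation_rad)
    k = t.scale_factor
    x = k * (c * p.x - s * p.y) + t.translation[0]
    y = k * (s * p.x + c * p.y) + t.translation[1]
    return PixelPoint(x=x, y=y, photo_id=t.target_photo_id)
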