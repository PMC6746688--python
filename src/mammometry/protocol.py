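"""Clinical measurement panel assembled from landmark annotations.

The panel comprises thirteen named linear measurements (all in cm):

========  =====================================================
NLD       nipple level difference (projected onto the midline)
MLN_R/L   medial line to nipple distance, right/left
SNN_R/L   sternal notch to nipple distance, right/left
IMFLD     inframammary fold apex level difference
IMFML_R/L inframammary fold apex to medial line distance
IMFN_R/L  inframammary fold apex to nipple distance
UPLD      upper pole apex level difference
UPN_R/L   upper pole apex to nipple distance
========  =====================================================

plus two aesthetic proportions per breast: the vertical upper:lower pole
ratio (ideal 45:55) and the horizontal lateral:medial ratio (ideal 40:60).

A subject may carry a secondary "breasts-lifted" photograph revealing the
inframammary folds and upper poles.  In that case IMFA/UPA landmarks are
taken from the lifted photo and mapped into the primary frame through the
midline-based similarity binding before any mixed-frame distance is
evaluated; nipples always come from the primary (relaxed) photo.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

from . import geometry as geo
from .errors import InvalidParameterError, MissingLandmarkError
from .geometry import CalibrationSegment, Midline, PixelPoint, Scale

logger = logging.getLogger(__name__)

__all__ = [
    "LANDMARK_VOCABULARY",
    "MEASUREMENT_NAMES",
    "IDEAL_VERTICAL_RATIO",
    "IDEAL_HORIZONTAL_RATIO",
    "LandmarkAnnotation",
    "MeasurementValue",
    "MeasurementPanel",
    "RatioSet",
    "compute_panel",
    "compute_ratios",
    "vertical_ratio",
    "horizontal_ratio",
]

#: Landmark vocabulary.  LB/MB (lateral/medial breast border) are optional
#: and only feed the horizontal aesthetic ratio.
LANDMARK_VOCABULARY = frozenset(
    {
        "SN", "UMB",
        "N_R", "N_L",
        "IMFA_R", "IMFA_L",
        "UPA_R", "UPA_L",
        "LB_R", "LB_L",
        "MB_R", "MB_L",
    }
)

#: Panel measurement names, in reporting order.
MEASUREMENT_NAMES = (
    "NLD",
    "MLN_R", "MLN_L",
    "SNN_R", "SNN_L",
    "IMFLD",
    "IMFML_R", "IMFML_L",
    "IMFN_R", "IMFN_L",
    "UPLD",
    "UPN_R", "UPN_L",
)

IDEAL_VERTICAL_RATIO: Tuple[float, float] = (45.0, 55.0)
IDEAL_HORIZONTAL_RATIO: Tuple[float, float] = (40.0, 60.0)

#: Landmarks that, when a lifted secondary photo is present, are read from
#: it instead of the relaxed primary photo.
_SECONDARY_PREFERRED = ("IMFA_R", "IMFA_L", "UPA_R", "UPA_L")


@dataclass
class LandmarkAnnotation:
    """Named pixel landmarks of one photo plus its calibration segment.

    ``secondary`` optionally holds the breasts-lifted companion photo's
    annotation (same schema, no further nesting).  Both the primary and a
    secondary annotation must contain SN and UMB.
    """

    photo_id: str
    calibration: CalibrationSegment
    landmarks: Dict[str, PixelPoint]
    secondary: Optional["LandmarkAnnotation"] = None
    lifted: bool = False
    image_size: Optional[Tuple[int, int]] = None  # (width, height) px
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.landmarks) - LANDMARK_VOCABULARY
        if unknown:
            raise InvalidParameterError(
                f"unknown landmark name(s) {sorted(unknown)}; "
                f"vocabulary is {sorted(LANDMARK_VOCABULARY)}"
            )
        for required in ("SN", "UMB"):
            if required not in self.landmarks:
                raise MissingLandmarkError(
                    f"annotation {self.photo_id!r} lacks required landmark {required}"
                )
        for name, point in self.landmarks.items():
            if point.photo_id is not None and point.photo_id != self.photo_id:
                raise InvalidParameterError(
                    f"landmark {name} carries frame {point.photo_id!r}, "
                    f"annotation is frame {self.photo_id!r}"
                )
        if self.secondary is not None and self.secondary.secondary is not None:
            raise InvalidParameterError("secondary annotations cannot nest further")

    @property
    def midline(self) -> Midline:
        return Midline(superior=self.landmarks["SN"], inferior=self.landmarks["UMB"])

    @property
    def scale(self) -> Scale:
        return geo.compute_scale(self.calibration)


@dataclass(frozen=True)
class MeasurementValue:
    value_cm: float
    provenance: str  # "single-photo" | "two-photo"

    def __post_init__(self) -> None:
        if not math.isfinite(self.value_cm) or self.value_cm < 0:
            raise InvalidParameterError(f"measurement must be finite and >= 0, got {self.value_cm}")
        if self.provenance not in ("single-photo", "two-photo"):
            raise InvalidParameterError(f"unknown provenance {self.provenance!r}")


@dataclass
class MeasurementPanel:
    """The named linear measurements of one subject, in centimetres.

    A measurement is present iff every landmark it requires was annotated;
    values are kept at full precision (round only for display).
    """

    values: Dict[str, MeasurementValue]

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(MEASUREMENT_NAMES)
        if unknown:
            raise InvalidParameterError(f"unknown measurement name(s) {sorted(unknown)}")

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __getitem__(self, name: str) -> float:
        return self.values[name].value_cm

    def get(self, name: str) -> Optional[float]:
        mv = self.values.get(name)
        return None if mv is None else mv.value_cm

    def provenance(self, name: str) -> str:
        return self.values[name].provenance

    def items(self) -> Iterable[Tuple[str, MeasurementValue]]:
        for name in MEASUREMENT_NAMES:
            if name in self.values:
                yield name, self.values[name]

    def as_records(self) -> list:
        """Rows (name, side, value_cm, provenance) for CSV serialisation."""
        records = []
        for name, mv in self.items():
            side = name[-1] if name.endswith(("_R", "_L")) else ""
            records.append(
                {
                    "name": name,
                    "side": side,
                    "value_cm": mv.value_cm,
                    "provenance": mv.provenance,
                }
            )
        return records

    def rounded(self, ndigits: int = 1) -> Dict[str, float]:
        """Tape-measure display precision (0.1 cm by default)."""
        return {name: round(mv.value_cm, ndigits) for name, mv in self.items()}


def vertical_ratio(upn_cm: float, imfn_cm: float) -> Tuple[float, float]:
    """Upper:lower pole proportion as percentages summing to 100.

    The published "most appealing" value is 45:55.
    """
    return _ratio(upn_cm, imfn_cm)


def horizontal_ratio(lateral_to_nipple_cm: float, nipple_to_medial_cm: float) -> Tuple[float, float]:
    """Lateral:medial proportion as percentages summing to 100 (ideal 40:60)."""
    return _ratio(lateral_to_nipple_cm, nipple_to_medial_cm)


def _ratio(a: float, b: float) -> Tuple[float, float]:
    if a < 0 or b < 0 or not (math.isfinite(a) and math.isfinite(b)):
        raise InvalidParameterError(f"ratio components must be finite and >= 0, got ({a}, {b})")
    total = a + b
    if total == 0:
        raise InvalidParameterError("undefined ratio: both components are zero")
    return (100.0 * a / total, 100.0 * b / total)


@dataclass
class RatioSet:
    """Aesthetic proportions per breast, with deviation from the ideals.

    Each entry maps side ("R"/"L") to an (upper%, lower%) or
    (lateral%, medial%) pair; sides with missing landmarks are absent.
    Deviations are in percentage points of the first component.
    """

    vertical: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    horizontal: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    ideal_vertical: Tuple[float, float] = IDEAL_VERTICAL_RATIO
    ideal_horizontal: Tuple[float, float] = IDEAL_HORIZONTAL_RATIO

    def vertical_deviation(self, side: str) -> float:
        return abs(self.vertical[side][0] - self.ideal_vertical[0])

    def horizontal_deviation(self, side: str) -> float:
        return abs(self.horizontal[side][0] - self.ideal_horizontal[0])


def _resolve_landmarks(annotation: LandmarkAnnotation) -> Tuple[Dict[str, PixelPoint], Dict[str, str]]:
    """Collapse a one- or two-photo annotation into primary-frame points.

    Returns the resolved landmark map and a per-landmark provenance map.
    IMFA/UPA prefer the lifted secondary photo when one is present; every
    other landmark always comes from the primary photo.
    """
    resolved = dict(annotation.landmarks)
    provenance = {name: "single-photo" for name in resolved}
    sec = annotation.secondary
    if sec is not None:
        transform = geo.bind_photos(
            annotation.midline,
            sec.midline,
            calibration_primary=annotation.calibration,
            calibration_secondary=sec.calibration,
        )
        for name in _SECONDARY_PREFERRED:
            if name in sec.landmarks:
                resolved[name] = geo.apply_transform(transform, sec.landmarks[name])
                provenance[name] = "two-photo"
    return resolved, provenance


def compute_panel(annotation: LandmarkAnnotation) -> MeasurementPanel:
    """Assemble the thirteen-measurement panel from an annotation.

    Measurements whose landmarks are missing are absent from the result
    (logged at DEBUG level), never reported as zero.
    """
    scale = annotation.scale
    midline = annotation.midline
    points, source = _resolve_landmarks(annotation)

    def prov(*names: str) -> str:
        return "two-photo" if any(source.get(n) == "two-photo" for n in names) else "single-photo"

    values: Dict[str, MeasurementValue] = {}

    def put(name: str, value: float, *landmarks_used: str) -> None:
        values[name] = MeasurementValue(value_cm=value, provenance=prov(*landmarks_used))

    def have(*names: str) -> bool:
        missing = [n for n in names if n not in points]
        if missing:
            logger.debug("skipping measurement: missing landmark(s) %s", missing)
            return False
        return True

    if have("N_R", "N_L"):
        put("NLD", geo.level_difference_cm(points["N_R"], points["N_L"], midline, scale)[1],
            "N_R", "N_L")
    if have("IMFA_R", "IMFA_L"):
        put("IMFLD", geo.level_difference_cm(points["IMFA_R"], points["IMFA_L"], midline, scale)[1],
            "IMFA_R", "IMFA_L")
    if have("UPA_R", "UPA_L"):
        put("UPLD", geo.level_difference_cm(points["UPA_R"], points["UPA_L"], midline, scale)[1],
            "UPA_R", "UPA_L")

    for side in ("R", "L"):
        n, imfa, upa = f"N_{side}", f"IMFA_{side}", f"UPA_{side}"
        if have(n):
            put(f"MLN_{side}", geo.midline_distance_cm(points[n], midline, scale), n)
            put(f"SNN_{side}", geo.distance_cm(points["SN"], points[n], scale), n)
        if have(imfa):
            put(f"IMFML_{side}", geo.midline_distance_cm(points[imfa], midline, scale), imfa)
        if have(imfa, n):
            put(f"IMFN_{side}", geo.distance_cm(points[imfa], points[n], scale), imfa, n)
        if have(upa, n):
            put(f"UPN_{side}", geo.distance_cm(points[upa], points[n], scale), upa, n)

    return MeasurementPanel(values=values)


def compute_ratios(annotation: LandmarkAnnotation, panel: Optional[MeasurementPanel] = None) -> RatioSet:
    """Aesthetic ratios derived from the panel and the optional LB/MB landmarks."""
    if panel is None:
        panel = compute_panel(annotation)
    scale = annotation.scale
    points, _ = _resolve_landmarks(annotation)
    ratios = RatioSet()
    for side in ("R", "L"):
        upn, imfn = panel.get(f"UPN_{side}"), panel.get(f"IMFN_{side}")
        if upn is not None and imfn is not None and upn + imfn > 0:
            ratios.vertical[side] = vertical_ratio(upn, imfn)
        lb, mb, n = f"LB_{side}", f"MB_{side}", f"N_{side}"
        if all(k in points for k in (lb, mb, n)):
            lateral = geo.distance_cm(points[lb], points[n], scale)
            medial = geo.distance_cm(points[n], points[mb], scale)
            if lateral + medial > 0:
                ratios.horizontal[side] = horizontal_ratio(lateral, medial)
    return ratios
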