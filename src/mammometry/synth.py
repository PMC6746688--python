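"""Synthetic subjects, photographs and observers for end-to-end testing.

Subjects live in a body-fixed centimetre frame with the sternal notch at
the origin, x toward the subject's left as seen by the camera, and y
increasing inferiorly (matching the image convention, so an identity
"photograph" is just a scale change).  The true midline is the vertical
axis x = 0, which makes every ground-truth panel value available in
closed form.

A photograph is a similarity transform of the body frame (pixel density,
camera roll, translation) plus an optional linear perspective-skew
coefficient; an observer is per-landmark Gaussian click jitter plus a
systematic bias, both in pixel space so that the centimetre error budget
scales inversely with pixel density, as it does for real photographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import CalibrationSegment, PixelPoint
from .protocol import (
    LANDMARK_VOCABULARY,
    MEASUREMENT_NAMES,
    LandmarkAnnotation,
    compute_panel,
)
from .stats import RepeatedMeasuresTable

__all__ = [
    "SubjectTemplate",
    "PhotoModel",
    "ObserverModel",
    "PRESETS",
    "make_subject",
    "ground_truth_panel",
    "photograph",
    "photograph_pair",
    "perturb",
    "batch_study",
]

#: Scale length (cm) over which the linear foreshortening coefficient acts.
_SKEW_REF_CM = 10.0

Coord = Tuple[float, float]


@dataclass(frozen=True)
class SubjectTemplate:
    """True landmark geometry of one synthetic subject, in body-frame cm."""

    landmarks_cm: Dict[str, Coord]
    preset: str
    ptosis: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.landmarks_cm) - LANDMARK_VOCABULARY
        if unknown:
            raise InvalidParameterError(f"unknown landmark(s) {sorted(unknown)}")
        for required in ("SN", "UMB"):
            if required not in self.landmarks_cm:
                raise InvalidParameterError(f"subject lacks {required}")
        sn, umb = self.landmarks_cm["SN"], self.landmarks_cm["UMB"]
        if not sn[1] < umb[1]:
            raise InvalidParameterError("sternal notch must sit superior to the umbilicus")
        for name, (x, _) in self.landmarks_cm.items():
            if name.endswith("_R") and x >= 0:
                raise InvalidParameterError(f"{name} must lie on the camera-left (x<0) side")
            if name.endswith("_L") and x <= 0:
                raise InvalidParameterError(f"{name} must lie on the camera-right (x>0) side")


@dataclass(frozen=True)
class PhotoModel:
    """Forward camera model mapping body-frame cm to pixel coordinates."""

    pixels_per_cm: float = 35.0
    roll_deg: float = 0.0
    translation_px: Coord = (900.0, 400.0)
    skew: float = 0.0
    reference_segment_cm: Tuple[Coord, Coord] = ((1.0, 4.0), (3.0, 4.0))

    def __post_init__(self) -> None:
        if self.pixels_per_cm <= 0 or not math.isfinite(self.pixels_per_cm):
            raise InvalidParameterError("pixels_per_cm must be positive")
        if not 0.0 <= self.skew <= 0.05:
            raise InvalidParameterError(f"skew coefficient must be in [0, 0.05], got {self.skew}")
        (ax, ay), (bx, by) = self.reference_segment_cm
        if not math.isclose(math.hypot(bx - ax, by - ay), 2.0, rel_tol=1e-9):
            raise InvalidParameterError("reference segment must be 2 cm long in the body frame")


@dataclass(frozen=True)
class ObserverModel:
    """Marker-placement noise of one observer: isotropic jitter + bias, in px."""

    jitter_sd_px: float = 2.0
    bias_px: Mapping[str, Coord] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd_px < 0:
            raise InvalidParameterError("jitter SD must be >= 0")


# Plausible body-frame geometry ranges (cm), drawn uniformly per subject.
PRESETS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "female": {
        "torso_len": (28.0, 36.0),
        "nipple_x": (8.0, 11.0),
        "nipple_y": (16.0, 22.0),
        "upa_dx": (-2.0, 0.5),     # UPA x offset from the nipple, toward midline
        "upa_dy": (6.0, 9.0),      # UPA sits this far superior to the nipple
        "imfa_x": (5.0, 8.0),
        "imfa_dy": (4.0, 7.0),     # IMFA sits this far inferior to the nipple
        "lb_dx": (6.0, 9.0),       # lateral border beyond the nipple
        "mb_x": (2.0, 4.0),        # medial border between midline and nipple
    },
    "male": {
        "torso_len": (30.0, 38.0),
        "nipple_x": (8.0, 11.0),
        "nipple_y": (14.0, 18.0),
        "upa_dx": (-1.0, 0.5),
        "upa_dy": (3.0, 5.0),
        "imfa_x": (4.0, 7.0),
        "imfa_dy": (2.0, 4.0),
        "lb_dx": (4.0, 7.0),
        "mb_x": (2.0, 4.0),
    },
}


def make_subject(
    preset: str = "female",
    asymmetry_cm: Optional[Mapping[str, Coord]] = None,
    seed: Optional[int] = None,
    ptosis: bool = False,
) -> SubjectTemplate:
    """Draw a subject from a preset's plausible ranges, then apply asymmetry.

    The base draw is perfectly mirror-symmetric; ``asymmetry_cm`` maps
    landmark names to (dx, dy) cm offsets applied afterwards, so
    ground-truth level differences equal the imposed dy offsets by
    construction.  Deterministic for a fixed seed.
    """
    if preset not in PRESETS:
        raise InvalidParameterError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    rng = np.random.default_rng(seed)
    p = PRESETS[preset]

    def draw(key: str) -> float:
        low, high = p[key]
        return float(rng.uniform(low, high))

    nipple_x, nipple_y = draw("nipple_x"), draw("nipple_y")
    upa_x = nipple_x + draw("upa_dx")
    upa_y = nipple_y - draw("upa_dy")
    imfa_x, imfa_y = draw("imfa_x"), nipple_y + draw("imfa_dy")
    lb_x = nipple_x + draw("lb_dx")
    mb_x = draw("mb_x")

    landmarks: Dict[str, Coord] = {"SN": (0.0, 0.0), "UMB": (0.0, draw("torso_len"))}
    for name, (x, y) in {
        "N": (nipple_x, nipple_y),
        "UPA": (upa_x, upa_y),
        "IMFA": (imfa_x, imfa_y),
        "LB": (lb_x, nipple_y),
        "MB": (mb_x, nipple_y),
    }.items():
        landmarks[f"{name}_R"] = (-x, y)  # subject's right = camera left
        landmarks[f"{name}_L"] = (x, y)

    for name, (dx, dy) in (asymmetry_cm or {}).items():
        if name not in landmarks:
            raise InvalidParameterError(f"asymmetry names unknown landmark {name!r}")
        x, y = landmarks[name]
        landmarks[name] = (x + dx, y + dy)

    return SubjectTemplate(landmarks_cm=landmarks, preset=preset, ptosis=ptosis)


def ground_truth_panel(subject: SubjectTemplate) -> Dict[str, float]:
    """Closed-form true panel: the body-frame midline is the axis x = 0.

    Levels are y-coordinates, midline distances are ``|x|`` and landmark
    distances are plain Euclidean norms — deliberately independent of the
    measurement pipeline so it can serve as an oracle.
    """
    lm = subject.landmarks_cm
    out: Dict[str, float] = {}
    for name, (right, left) in (("NLD", ("N_R", "N_L")),
                                ("IMFLD", ("IMFA_R", "IMFA_L")),
                                ("UPLD", ("UPA_R", "UPA_L"))):
        if right in lm and left in lm:
            out[name] = abs(lm[right][1] - lm[left][1])
    for side in ("R", "L"):
        n = lm.get(f"N_{side}")
        if n is not None:
            out[f"MLN_{side}"] = abs(n[0])
            out[f"SNN_{side}"] = math.hypot(n[0], n[1])
        imfa = lm.get(f"IMFA_{side}")
        if imfa is not None:
            out[f"IMFML_{side}"] = abs(imfa[0])
            if n is not None:
                out[f"IMFN_{side}"] = math.hypot(imfa[0] - n[0], imfa[1] - n[1])
        upa = lm.get(f"UPA_{side}")
        if upa is not None and n is not None:
            out[f"UPN_{side}"] = math.hypot(upa[0] - n[0], upa[1] - n[1])
    return out


def _project(photo: PhotoModel, xy: Coord) -> Coord:
    """Body-frame cm -> pixel coordinates under the photo model."""
    x, y = xy
    # Linear foreshortening: lateral offsets shrink with inferior position.
    x = x * (1.0 - photo.skew * y / _SKEW_REF_CM)
    theta = math.radians(photo.roll_deg)
    c, s = math.cos(theta), math.sin(theta)
    k = photo.pixels_per_cm
    return (
        k * (c * x - s * y) + photo.translation_px[0],
        k * (s * x + c * y) + photo.translation_px[1],
    )


def photograph(
    subject: SubjectTemplate,
    photo: Optional[PhotoModel] = None,
    photo_id: str = "primary",
    include: Optional[Sequence[str]] = None,
    lifted: bool = False,
) -> LandmarkAnnotation:
    """Noise-free annotation of a subject under a photo model.

    ``include`` restricts the landmark set (SN/UMB are always kept); by
    default a ptotic subject's relaxed photo omits IMFA and UPA, which are
    only visible on a lifted photo.
    """
    photo = photo or PhotoModel()
    names = set(include) if include is not None else set(subject.landmarks_cm)
    names |= {"SN", "UMB"}
    if include is None and subject.ptosis and not lifted:
        names -= {"IMFA_R", "IMFA_L", "UPA_R", "UPA_L"}
    landmarks = {
        name: PixelPoint(*_project(photo, subject.landmarks_cm[name]), photo_id=photo_id)
        for name in sorted(names & set(subject.landmarks_cm))
    }
    ref_a, ref_b = photo.reference_segment_cm
    calibration = CalibrationSegment(
        endpoint_a=PixelPoint(*_project(photo, ref_a), photo_id=photo_id),
        endpoint_b=PixelPoint(*_project(photo, ref_b), photo_id=photo_id),
        known_length_cm=2.0,
    )
    return LandmarkAnnotation(
        photo_id=photo_id,
        calibration=calibration,
        landmarks=landmarks,
        lifted=lifted,
    )


def photograph_pair(
    subject: SubjectTemplate,
    photo_primary: Optional[PhotoModel] = None,
    photo_secondary: Optional[PhotoModel] = None,
) -> LandmarkAnnotation:
    """Relaxed + lifted photo pair for a ptotic subject, already linked."""
    primary = photograph(subject, photo_primary, photo_id="primary")
    secondary = photograph(
        subject,
        photo_secondary or PhotoModel(),
        photo_id="secondary",
        include=("SN", "UMB", "IMFA_R", "IMFA_L", "UPA_R", "UPA_L"),
        lifted=True,
    )
    primary.secondary = secondary
    return primary


def perturb(
    annotation: LandmarkAnnotation,
    observer: ObserverModel,
    session_seed: int,
) -> LandmarkAnnotation:
    """Apply one observer's bias + click jitter to every marker.

    The calibration endpoints are jittered too, so calibration error
    propagates into every centimetre value.  Deterministic per
    (observer.seed, session_seed).
    """
    rng = np.random.default_rng([observer.seed, session_seed])

    def jitter(p: PixelPoint, name: Optional[str] = None) -> PixelPoint:
        bx, by = observer.bias_px.get(name, (0.0, 0.0)) if name else (0.0, 0.0)
        dx, dy = rng.normal(0.0, observer.jitter_sd_px, size=2)
        return PixelPoint(p.x + bx + dx, p.y + by + dy, photo_id=p.photo_id)

    landmarks = {name: jitter(p, name) for name, p in sorted(annotation.landmarks.items())}
    calibration = CalibrationSegment(
        endpoint_a=jitter(annotation.calibration.endpoint_a),
        endpoint_b=jitter(annotation.calibration.endpoint_b),
        known_length_cm=annotation.calibration.known_length_cm,
    )
    secondary = annotation.secondary
    if secondary is not None:
        secondary = perturb(secondary, observer, session_seed + 7919)
    return LandmarkAnnotation(
        photo_id=annotation.photo_id,
        calibration=calibration,
        landmarks=landmarks,
        secondary=secondary,
        lifted=annotation.lifted,
        image_size=annotation.image_size,
        metadata=dict(annotation.metadata),
    )


def batch_study(
    n_subjects: int,
    n_observers: int = 2,
    n_sessions: int = 3,
    preset: str = "female",
    master_seed: int = 0,
    observer_models: Optional[Sequence[ObserverModel]] = None,
    asymmetry_sd_cm: float = 0.5,
    reference_noise_sd_cm: float = 0.0,
    ptosis_fraction: float = 0.0,
) -> RepeatedMeasuresTable:
    """Simulate a complete repeated-measures validation study.

    Each subject gets one randomized photo model (pixel density, roll,
    translation); each observer re-marks every photo in every session.
    References are the closed-form ground-truth panels, optionally
    perturbed by a tape-measure noise SD to emulate imperfect direct
    measurement.  Fully deterministic under ``master_seed``.
    """
    if n_subjects < 2:
        raise InvalidParameterError("need >= 2 subjects")
    if n_observers < 1 or n_sessions < 1:
        raise InvalidParameterError("need >= 1 observer and session")
    rng = np.random.default_rng(master_seed)
    if observer_models is None:
        observer_models = [
            ObserverModel(
                jitter_sd_px=2.0,
                bias_px={"N_R": tuple(rng.normal(0, 1, 2)), "N_L": tuple(rng.normal(0, 1, 2))},
                seed=int(rng.integers(2**31)) ,
            )
            for _ in range(n_observers)
        ]
    if len(observer_models) != n_observers:
        raise InvalidParameterError("observer_models length must equal n_observers")

    rows, ref_rows = [], []
    for i in range(n_subjects):
        asym = {
            name: (float(rng.normal(0, asymmetry_sd_cm)), float(rng.normal(0, asymmetry_sd_cm)))
            for name in ("N_L", "IMFA_L", "UPA_L")
        }
        ptotic = bool(rng.random() < ptosis_fraction)
        subject = make_subject(
            preset=preset,
            asymmetry_cm=asym,
            seed=int(rng.integers(2**31)),
            ptosis=ptotic,
        )
        photo = PhotoModel(
            pixels_per_cm=float(rng.uniform(25, 45)),
            roll_deg=float(rng.uniform(-10, 10)),
            translation_px=(float(rng.uniform(600, 1200)), float(rng.uniform(200, 600))),
        )
        if ptotic:
            lifted_photo = PhotoModel(
                pixels_per_cm=float(rng.uniform(25, 45)),
                roll_deg=float(rng.uniform(-10, 10)),
                translation_px=(float(rng.uniform(600, 1200)), float(rng.uniform(200, 600))),
            )
            annotation = photograph_pair(subject, photo, lifted_photo)
        else:
            annotation = photograph(subject, photo)

        subject_id = f"S{i:03d}"
        truth = ground_truth_panel(subject)
        for name in MEASUREMENT_NAMES:
            if name in truth:
                ref = truth[name]
                if reference_noise_sd_cm > 0:
                    ref = max(0.0, ref + float(rng.normal(0, reference_noise_sd_cm)))
                ref_rows.append(
                    {"subject_id": subject_id, "measurement": name, "reference_cm": ref}
                )
        for o, observer in enumerate(observer_models):
            for session in range(1, n_sessions + 1):
                session_seed = int(rng.integers(2**31))
                marked = perturb(annotation, observer, session_seed)
                panel = compute_panel(marked)
                for name, mv in panel.items():
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "observer_id": f"O{o + 1}",
                            "session": session,
                            "measurement": name,
                            "value_cm": mv.value_cm,
                        }
                    )
    return RepeatedMeasuresTable(pd.DataFrame(rows), pd.DataFrame(ref_rows))
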