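"""Reading and writing annotation files (versioned JSON schema).

An annotation file carries subject metadata and one or two photo blocks;
each block records the photo's identifier, optional image path and pixel
dimensions, the calibration segment, and the named landmark map.  Exactly
one block has role ``primary``; an optional second block with role
``secondary`` holds the breasts-lifted photo.

Validation is performed with pydantic models; a static JSON Schema export
is shipped at ``mammometry/data/annotation.schema.json`` for third-party
tooling.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import AnnotationSchemaError
from .geometry import CalibrationSegment, PixelPoint
from .protocol import LANDMARK_VOCABULARY, LandmarkAnnotation

__all__ = ["SCHEMA_VERSION", "read_annotation", "write_annotation", "AnnotationFileModel"]

SCHEMA_VERSION = 1


class CalibrationModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    endpoint_a: Tuple[float, float]
    endpoint_b: Tuple[float, float]
    known_length_cm: float = Field(default=2.0, gt=0)


class PhotoBlockModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    photo_id: str
    role: str = Field(pattern="^(primary|secondary)$")
    image_path: Optional[str] = None
    width_px: Optional[int] = Field(default=None, gt=0)
    height_px: Optional[int] = Field(default=None, gt=0)
    calibration: CalibrationModel
    landmarks: Dict[str, Tuple[float, float]]

    @field_validator("landmarks")
    @classmethod
    def _known_names(cls, v: Dict[str, Tuple[float, float]]):
        unknown = set(v) - LANDMARK_VOCABULARY
        if unknown:
            raise ValueError(
                f"unknown landmark name(s) {sorted(unknown)}; "
                f"allowed: {sorted(LANDMARK_VOCABULARY)}"
            )
        for required in ("SN", "UMB"):
            if required not in v:
                raise ValueError(f"missing required landmark {required}")
        return v


class SubjectModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    sex_type: Optional[str] = Field(default=None, pattern="^(female|male)$")
    notes: Optional[str] = None


class AnnotationFileModel(BaseModel):
    """Top-level annotation document."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int
    subject: SubjectModel
    photos: List[PhotoBlockModel] = Field(min_length=1, max_length=2)

    @field_validator("schema_version")
    @classmethod
    def _version(cls, v: int) -> int:
        if v != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {v}; expected {SCHEMA_VERSION}")
        return v

    @field_validator("photos")
    @classmethod
    def _one_primary(cls, photos: List[PhotoBlockModel]):
        roles = [p.role for p in photos]
        if roles.count("primary") != 1:
            raise ValueError(f"exactly one photo must have role 'primary', got roles {roles}")
        if len(photos) == 2 and "secondary" not in roles:
            raise ValueError("the second photo block must have role 'secondary'")
        return photos


def _block_to_annotation(block: PhotoBlockModel) -> LandmarkAnnotation:
    def pt(xy: Tuple[float, float]) -> PixelPoint:
        return PixelPoint(x=xy[0], y=xy[1], photo_id=block.photo_id)

    size = None
    if block.width_px is not None and block.height_px is not None:
        size = (block.width_px, block.height_px)
    return LandmarkAnnotation(
        photo_id=block.photo_id,
        calibration=CalibrationSegment(
            endpoint_a=pt(block.calibration.endpoint_a),
            endpoint_b=pt(block.calibration.endpoint_b),
            known_length_cm=block.calibration.known_length_cm,
        ),
        landmarks={name: pt(xy) for name, xy in block.landmarks.items()},
        lifted=block.role == "secondary",
        image_size=size,
        metadata={"image_path": block.image_path} if block.image_path else {},
    )


def read_annotation(path) -> LandmarkAnnotation:
    """Parse and validate an annotation file into a typed annotation.

    The primary photo's annotation is returned; a secondary block, when
    present, is attached as ``.secondary``.  Subject metadata lands in
    ``.metadata["subject"]``.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise AnnotationSchemaError(f"cannot read annotation {path}: {exc}") from exc
    try:
        doc = AnnotationFileModel.model_validate(raw)
    except ValidationError as exc:
        fields = "; ".join(
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise AnnotationSchemaError(f"invalid annotation {path}: {fields}") from exc

    primary_block = next(p for p in doc.photos if p.role == "primary")
    annotation = _block_to_annotation(primary_block)
    for block in doc.photos:
        if block.role == "secondary":
            annotation.secondary = _block_to_annotation(block)
    annotation.metadata["subject"] = doc.subject.model_dump()
    return annotation


def write_annotation(annotation: LandmarkAnnotation, path, subject_id: str = "anonymous") -> None:
    """Serialise an annotation (and its optional secondary photo) to JSON."""

    def block(a: LandmarkAnnotation, role: str) -> dict:
        out = {
            "photo_id": a.photo_id,
            "role": role,
            "calibration": {
                "endpoint_a": [a.calibration.endpoint_a.x, a.calibration.endpoint_a.y],
                "endpoint_b": [a.calibration.endpoint_b.x, a.calibration.endpoint_b.y],
                "known_length_cm": a.calibration.known_length_cm,
            },
            "landmarks": {name: [p.x, p.y] for name, p in sorted(a.landmarks.items())},
        }
        if a.image_size is not None:
            out["width_px"], out["height_px"] = a.image_size
        if a.metadata.get("image_path"):
            out["image_path"] = a.metadata["image_path"]
        return out

    meta = annotation.metadata.get("subject") or {}
    doc = {
        "schema_version": SCHEMA_VERSION,
        "subject": {
            "id": meta.get("id", subject_id),
            "sex_type": meta.get("sex_type"),
            "notes": meta.get("notes"),
        },
        "photos": [block(annotation, "primary")],
    }
    if annotation.secondary is not None:
        doc["photos"].append(block(annotation.secondary, "secondary"))
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def export_json_schema(path) -> None:
    """Write the machine-readable JSON Schema for annotation files."""
    Path(path).write_text(
        json.dumps(AnnotationFileModel.model_json_schema(), indent=2, sort_keys=True) + "\n"
    )
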