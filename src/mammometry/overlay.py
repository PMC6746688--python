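"""Deterministic SVG overlay of markers, midline and measurement lines.

The overlay is pure vector graphics referencing the photo coordinates, so
it can be laid over the original image (linked by path, never embedded)
or rendered on a blank canvas of the annotation's declared dimensions.
Identical inputs always produce byte-identical SVG.
"""

from __future__ import annotations

from typing import Optional, Tuple

from .errors import InvalidParameterError
from .protocol import LandmarkAnnotation, MeasurementPanel, compute_panel

__all__ = ["render_overlay"]

_MARKER_RADIUS = 6
_COLORS = {"marker": "#d62728", "midline": "#1f77b4", "measure": "#2ca02c"}


def _fmt(v: float) -> str:
    return f"{v:.3f}".rstrip("0").rstrip(".")


def render_overlay(
    annotation: LandmarkAnnotation,
    panel: Optional[MeasurementPanel] = None,
    image_path: Optional[str] = None,
    image_size: Optional[Tuple[int, int]] = None,
) -> str:
    """Render the primary photo's annotation as an SVG string.

    Draws one ``marker`` circle per landmark, the ``midline`` segment, and
    one ``measure-line`` per computable landmark-to-landmark or
    level-difference measurement (midline distances are implied by the
    perpendicular geometry and not drawn).  When an image is referenced
    its dimensions must match the annotation's declared size.
    """
    if panel is None:
        panel = compute_panel(annotation)
    size = image_size or annotation.image_size or (1800, 1200)
    if image_path is not None and annotation.image_size is not None and image_size is not None:
        if tuple(image_size) != tuple(annotation.image_size):
            raise InvalidParameterError(
                f"image dimensions {image_size} mismatch annotation "
                f"dimensions {annotation.image_size}"
            )
    width, height = size
    lm = annotation.landmarks
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">'
    ]
    if image_path is not None:
        parts.append(
            f'<image href="{image_path}" x="0" y="0" width="{width}" height="{height}"/>'
        )
    else:
        parts.append(f'<rect x="0" y="0" width="{width}" height="{height}" fill="#f5f5f5"/>')

    sn, umb = lm["SN"], lm["UMB"]
    parts.append(
        f'<line class="midline" x1="{_fmt(sn.x)}" y1="{_fmt(sn.y)}" '
        f'x2="{_fmt(umb.x)}" y2="{_fmt(umb.y)}" stroke="{_COLORS["midline"]}" stroke-width="2"/>'
    )

    # one line per direct landmark-pair measurement present in the panel
    segment_defs = (
        ("SNN_R", "SN", "N_R"), ("SNN_L", "SN", "N_L"),
        ("IMFN_R", "IMFA_R", "N_R"), ("IMFN_L", "IMFA_L", "N_L"),
        ("UPN_R", "UPA_R", "N_R"), ("UPN_L", "UPA_L", "N_L"),
        ("NLD", "N_R", "N_L"), ("IMFLD", "IMFA_R", "IMFA_L"), ("UPLD", "UPA_R", "UPA_L"),
    )
    for measurement, a, b in segment_defs:
        if measurement in panel and a in lm and b in lm:
            pa, pb = lm[a], lm[b]
            parts.append(
                f'<line class="measure-line" data-measurement="{measurement}" '
                f'x1="{_fmt(pa.x)}" y1="{_fmt(pa.y)}" x2="{_fmt(pb.x)}" y2="{_fmt(pb.y)}" '
                f'stroke="{_COLORS["measure"]}" stroke-width="1.5" stroke-dasharray="6 3"/>'
            )

    for name in sorted(lm):
        p = lm[name]
        parts.append(
            f'<circle class="marker" data-landmark="{name}" cx="{_fmt(p.x)}" cy="{_fmt(p.y)}" '
            f'r="{_MARKER_RADIUS}" fill="{_COLORS["marker"]}"/>'
        )
        parts.append(
            f'<text x="{_fmt(p.x + 9)}" y="{_fmt(p.y - 9)}" font-size="18" '
            f'font-family="sans-serif" fill="{_COLORS["marker"]}">{name}</text>'
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
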