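"""Measurement report assembly (structured JSON + printable HTML).

Reports are regenerable: the same annotation always yields bit-identical
output.  Human-readable lengths are rounded to 0.1 cm (tape-measure
precision); the JSON form keeps full precision alongside the rounded
display value.
"""

from __future__ import annotations

import json
from typing import Dict, Optional

from .overlay import render_overlay
from .protocol import (
    IDEAL_HORIZONTAL_RATIO,
    IDEAL_VERTICAL_RATIO,
    LandmarkAnnotation,
    MeasurementPanel,
    RatioSet,
    compute_panel,
    compute_ratios,
)

__all__ = ["build_report", "report_json", "report_html"]


def build_report(
    annotation: LandmarkAnnotation,
    panel: Optional[MeasurementPanel] = None,
    ratios: Optional[RatioSet] = None,
) -> Dict:
    """Structured report: panel, ratios, provenance and subject metadata."""
    if panel is None:
        panel = compute_panel(annotation)
    if ratios is None:
        ratios = compute_ratios(annotation, panel)
    measurements = {
        name: {
            "value_cm": mv.value_cm,
            "display_cm": round(mv.value_cm, 1),
            "provenance": mv.provenance,
        }
        for name, mv in panel.items()
    }
    ratio_block = {
        "vertical": {
            side: {
                "upper_percent": pair[0],
                "lower_percent": pair[1],
                "ideal": list(IDEAL_VERTICAL_RATIO),
                "deviation_pp": ratios.vertical_deviation(side),
            }
            for side, pair in sorted(ratios.vertical.items())
        },
        "horizontal": {
            side: {
                "lateral_percent": pair[0],
                "medial_percent": pair[1],
                "ideal": list(IDEAL_HORIZONTAL_RATIO),
                "deviation_pp": ratios.horizontal_deviation(side),
            }
            for side, pair in sorted(ratios.horizontal.items())
        },
    }
    return {
        "subject": annotation.metadata.get("subject", {}),
        "photo_ids": [annotation.photo_id]
        + ([annotation.secondary.photo_id] if annotation.secondary else []),
        "two_photo": annotation.secondary is not None,
        "measurements": measurements,
        "ratios": ratio_block,
    }


def report_json(annotation: LandmarkAnnotation, **kwargs) -> str:
    return json.dumps(build_report(annotation, **kwargs), indent=2, sort_keys=True) + "\n"


_HTML_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>Measurement report: {subject_id}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 4px 10px; text-align: right; }}
th {{ background: #eee; }}
</style></head>
<body>
<h1>Breast measurement report</h1>
<p>Subject: <b>{subject_id}</b>{sex}&nbsp;&mdash; {mode}</p>
<table>
<tr><th>Measurement</th><th>Value (cm)</th><th>Source</th></tr>
{rows}
</table>
{ratio_section}
<div>{overlay}</div>
</body>
</html>
"""


def report_html(annotation: LandmarkAnnotation, **kwargs) -> str:
    """Printable page: measurement table, ratios and the SVG overlay inline."""
    doc = build_report(annotation, **kwargs)
    rows = "\n".join(
        f"<tr><td>{name}</td><td>{entry['display_cm']:.1f}</td>"
        f"<td>{entry['provenance']}</td></tr>"
        for name, entry in doc["measurements"].items()
    )
    ratio_lines = []
    for side, entry in doc["ratios"]["vertical"].items():
        ratio_lines.append(
            f"<li>Vertical ({side}): {entry['upper_percent']:.0f}:{entry['lower_percent']:.0f}"
            f" (ideal 45:55, deviation {entry['deviation_pp']:.1f} pp)</li>"
        )
    for side, entry in doc["ratios"]["horizontal"].items():
        ratio_lines.append(
            f"<li>Horizontal ({side}): {entry['lateral_percent']:.0f}:{entry['medial_percent']:.0f}"
            f" (ideal 40:60, deviation {entry['deviation_pp']:.1f} pp)</li>"
        )
    ratio_section = f"<h2>Aesthetic proportions</h2><ul>{''.join(ratio_lines)}</ul>" if ratio_lines else ""
    subject = doc["subject"]
    return _HTML_TEMPLATE.format(
        subject_id=subject.get("id", "anonymous"),
        sex=f" ({subject['sex_type']})" if subject.get("sex_type") else "",
        mode="two-photo assessment" if doc["two_photo"] else "single-photo assessment",
        rows=rows,
        ratio_section=ratio_section,
        overlay=render_overlay(annotation),
    )
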