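"""Annotation and report serialization.

Annotations are JSON with an explicit schema version: one file holds one or
more films, each with the four named pelvic landmarks, the rim points, the
operated side and the mm-per-unit scale. JSON keeps hand-editing and test
fixtures trivial; reports export to CSV (clinical spreadsheet use) or JSON
with angles rounded to 2 decimals, matching how such measurements are
reported.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .decision import VersionDecision
from .errors import AnnotationSchemaError, InvalidMeasurementError
from .measure import CupMeasurement, LandmarkSet, Point2D

__all__ = [
    "ANNOTATION_SCHEMA_VERSION",
    "read_annotations",
    "write_annotations",
    "write_report",
    "report_tables",
]

ANNOTATION_SCHEMA_VERSION = 1


class _FilmModel(BaseModel):
    left_teardrop: tuple[float, float]
    right_teardrop: tuple[float, float]
    scj: tuple[float, float]
    ps: tuple[float, float]
    rim_points: list[tuple[float, float]] = Field(min_length=5)
    side: Literal["left", "right"]
    scale_mm_per_unit: float = Field(default=1.0, gt=0.0)


class _AnnotationModel(BaseModel):
    schema_version: Literal[1]
    films: list[_FilmModel] = Field(min_length=1)
    provenance: str = ""


def read_annotations(path: str | Path) -> list[LandmarkSet]:
    """Read and validate a landmark annotation file.

    Raises :class:`AnnotationSchemaError` naming the offending field when
    the file does not conform to the schema.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationSchemaError(f"{path}: not valid JSON: {exc}") from exc
    try:
        model = _AnnotationModel.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(loc) for loc in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        )
        raise AnnotationSchemaError(f"{path}: {details}") from exc
    return [
        LandmarkSet(
            left_teardrop=Point2D(*film.left_teardrop),
            right_teardrop=Point2D(*film.right_teardrop),
            scj=Point2D(*film.scj),
            ps=Point2D(*film.ps),
            rim_points=film.rim_points,
            side=film.side,
            scale_mm_per_unit=film.scale_mm_per_unit,
        )
        for film in model.films
    ]


def write_annotations(
    landmark_sets: list[LandmarkSet], path: str | Path, provenance: str = ""
) -> None:
    """Write landmark sets as a canonical annotation file (stable key order
    and formatting, so read -> write round trips are byte-identical)."""
    if not landmark_sets:
        raise ValueError("no landmark sets to write")
    doc = {
        "schema_version": ANNOTATION_SCHEMA_VERSION,
        "films": [
            {
                "left_teardrop": list(lm.left_teardrop),
                "right_teardrop": list(lm.right_teardrop),
                "scj": list(lm.scj),
                "ps": list(lm.ps),
                "rim_points": [list(p) for p in lm.rim_points],
                "side": lm.side,
                "scale_mm_per_unit": lm.scale_mm_per_unit,
            }
            for lm in landmark_sets
        ],
        "provenance": provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _round2(value: float | None) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return round(float(value), 2)


def report_tables(
    measurements: list[CupMeasurement], decision: VersionDecision | None
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Build the per-film table and (optionally) the decision table with all
    angles rounded to 2 decimals. Deterministic given the inputs."""
    if not measurements:
        raise InvalidMeasurementError("no measurements to report")
    film_rows = []
    for i, m in enumerate(measurements, start=1):
        film_rows.append(
            {
                "film": i,
                "side": m.side,
                "inclination_deg": _round2(m.inclination_deg),
                "planar_version_deg": _round2(m.planar_version_deg),
                "liaw_v1_deg": _round2(m.liaw_v1_deg),
                "liaw_v2_deg": _round2(m.liaw_v2_deg),
                "rotation_deg": _round2(m.pose.rotation_deg) if m.pose else None,
                "flexion_deg": _round2(m.pose.flexion_deg) if m.pose else None,
                "axis_ratio": (
                    round(m.pose.axis_ratio, 4) if m.pose is not None else None
                ),
            }
        )
    films = pd.DataFrame(film_rows)
    if decision is None:
        return films, None
    dec = pd.DataFrame(
        [
            {
                "delta_ante_deg": _round2(decision.delta_ante_deg),
                "delta_retro_deg": _round2(decision.delta_retro_deg),
                "label": decision.label,
                "final_version_deg": _round2(decision.final_version_deg),
                "pose_separation_deg": _round2(decision.pose_separation_deg),
            }
        ]
    )
    return films, dec


def write_report(
    measurements: list[CupMeasurement],
    decision: VersionDecision | None,
    path: str | Path,
    format: Literal["csv", "json"] = "csv",
) -> None:
    """Write a measurement report.

    CSV: the per-film table, a blank line, then the decision table.
    JSON: ``{"films": [...], "decision": {...}}``. Both formats encode the
    same rounded numbers.
    """
    films, dec = report_tables(measurements, decision)
    path = Path(path)
    if format == "csv":
        text = films.to_csv(index=False)
        if dec is not None:
            text += "\n" + dec.to_csv(index=False)
        path.write_text(text)
    elif format == "json":
        doc = {"films": films.to_dict(orient="records")}
        if dec is not None:
            doc["decision"] = dec.to_dict(orient="records")[0]
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
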