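"""Polygon annotation reading/writing (GeoJSON-like JSON).

A polygon is a list of [row, col] vertices, first vertex not repeated,
implicitly closed. Files hold either a bare list of polygons or objects
with optional holes; :func:`polygon_area` uses the shoelace convention
(outer area minus holes) via shapely.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

__all__ = ["read_annotation", "write_annotation", "polygon_area", "AnnotationError"]


class AnnotationError(ValueError):
    """Malformed annotation file or degenerate polygon."""


def _validate_ring(ring, where: str) -> list[list[float]]:
    if not isinstance(ring, (list, tuple)) or len(ring) < 3:
        raise AnnotationError(f"{where}: polygon needs at least 3 vertices")
    out = []
    for i, vertex in enumerate(ring):
        if (not isinstance(vertex, (list, tuple)) or len(vertex) != 2
                or not all(isinstance(v, (int, float)) for v in vertex)):
            raise AnnotationError(f"{where}, vertex {i}: expected [row, col] numbers")
        out.append([float(vertex[0]), float(vertex[1])])
    if out[0] == out[-1]:
        raise AnnotationError(f"{where}: first vertex must not repeat as last "
                              "(rings are implicitly closed)")
    return out


def read_annotation(path: str | Path) -> list[dict]:
    """Read polygons from JSON; returns a list of {"exterior": (n,2) array,
    "holes": [(m,2) arrays]} dicts."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: invalid JSON ({exc.msg} at line {exc.lineno})")
    if not isinstance(data, list):
        raise AnnotationError(f"{path}: top level must be a list of polygons")
    polygons = []
    for i, item in enumerate(data):
        where = f"{path}: polygon {i}"
        if isinstance(item, dict):
            exterior = _validate_ring(item.get("exterior"), where)
            holes = [_validate_ring(h, f"{where} hole {j}")
                     for j, h in enumerate(item.get("holes", []))]
        else:
            exterior = _validate_ring(item, where)
            holes = []
        polygons.append({"exterior": np.array(exterior),
                         "holes": [np.array(h) for h in holes]})
    return polygons


def write_annotation(path: str | Path, polygons) -> None:
    """Write polygons to JSON. Accepts (n,2) vertex arrays or dicts as
    returned by :func:`read_annotation`; round-trips vertices exactly."""
    out = []
    for poly in polygons:
        if isinstance(poly, dict):
            entry = {"exterior": np.asarray(poly["exterior"], dtype=float).tolist()}
            holes = [np.asarray(h, dtype=float).tolist() for h in poly.get("holes", [])]
            if holes:
                entry["holes"] = holes
            out.append(entry)
        else:
            out.append(np.asarray(poly, dtype=float).tolist())
    Path(path).write_text(json.dumps(out, indent=1) + "\n")


def polygon_area(polygon: dict | np.ndarray) -> float:
    """Shoelace area: exterior minus holes."""
    if isinstance(polygon, dict):
        return Polygon(polygon["exterior"],
                       [h for h in polygon.get("holes", [])]).area
    return Polygon(np.asarray(polygon)).area
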