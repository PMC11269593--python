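"""GeoJSON and CSV I/O for point tables and line/polygon geometries.

CRS handling matches the raster side: an opaque identifier is carried in a
GeoJSON foreign member (``crs_id``) and never interpreted.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .grids import PointTable

__all__ = [
    "write_geometries",
    "read_geometries",
    "write_points_csv",
    "read_points_csv",
]


def write_geometries(geometries, path, crs_id: str = "local") -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": {"id": i}}
        for i, g in enumerate(geometries)
    ]
    doc = {"type": "FeatureCollection", "crs_id": crs_id, "features": features}
    Path(path).write_text(json.dumps(doc))


def read_geometries(path) -> tuple[list, str]:
    doc = json.loads(Path(path).read_text())
    geoms = [shape(feat["geometry"]) for feat in doc["features"]]
    return geoms, doc.get("crs_id", "local")


def write_points_csv(points: PointTable, path) -> None:
    points.data.to_csv(path, index=False)


def read_points_csv(path, crs_id: str = "local") -> PointTable:
    return PointTable(pd.read_csv(path), crs_id=crs_id)
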