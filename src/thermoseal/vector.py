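"""GeoJSON I/O for detections and annotation points.

Detections are written as RFC 7946 FeatureCollections with per-feature
attributes (class, area_m2, mean_temp_c, chull_ratio, pixel_count,
parent_id). Annotation points (human-placed, class-labeled) are read from
GeoJSON or CSV with columns id, x, y, label.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .detect import ClassLabel, SealPolygon

__all__ = [
    "write_detections",
    "read_detections",
    "read_points",
    "write_points",
]


def write_detections(detections: list[SealPolygon], path) -> None:
    """Write detections to a GeoJSON FeatureCollection."""
    features = []
    for det in detections:
        features.append({
            "type": "Feature",
            "id": det.id,
            "geometry": mapping(det.geometry),
            "properties": {
                "id": det.id,
                "class": det.label.value,
                "area_m2": det.area_m2,
                "mean_temp_c": det.mean_temp_c,
                "chull_ratio": det.chull_ratio,
                "pixel_count": det.pixel_count,
                "parent_id": det.parent_id,
            },
        })
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def read_detections(path) -> list[SealPolygon]:
    with open(path) as fh:
        doc = json.load(fh)
    out = []
    for feat in doc["features"]:
        props = feat["properties"]
        out.append(SealPolygon(
            id=int(props["id"]),
            geometry=shape(feat["geometry"]),
            pixel_count=int(props["pixel_count"]),
            area_m2=float(props["area_m2"]),
            mean_temp_c=float(props["mean_temp_c"]),
            chull_ratio=float(props["chull_ratio"]),
            label=ClassLabel(props["class"]),
            parent_id=None if props.get("parent_id") is None else int(props["parent_id"]),
        ))
    return out


def read_points(path) -> "list":
    """Read annotation points from CSV (id,x,y,label) or GeoJSON points."""
    from .assess import GroundTruthPoint

    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            doc = json.load(fh)
        pts = []
        for i, feat in enumerate(doc["features"]):
            geom = shape(feat["geometry"])
            props = feat.get("properties") or {}
            pts.append(GroundTruthPoint(
                id=int(props.get("id", i)),
                x=geom.x, y=geom.y,
                label=str(props["label"]),
            ))
        return pts
    df = pd.read_csv(path)
    return [
        GroundTruthPoint(id=int(r.id), x=float(r.x), y=float(r.y), label=str(r.label))
        for r in df.itertuples(index=False)
    ]


def write_points(points, path) -> None:
    """Write annotation points as CSV (id,x,y,label) or GeoJSON by suffix."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        features = [{
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
            "properties": {"id": p.id, "label": p.label},
        } for p in points]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
            fh.write("\n")
    else:
        df = pd.DataFrame(
            [(p.id, p.x, p.y, p.label) for p in points],
            columns=["id", "x", "y", "label"],
        )
        df.to_csv(path, index=False)
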