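"""Reading and writing the pipeline's file formats.

Vector data is exchanged as GeoJSON (LineString street layers, Point site
layers, Polygon block layers); tabular data as CSV.  Attribute names of
input layers are mapped via keyword arguments, so datasets with different
schemas (class field, bridge flag) can be ingested without editing them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from shapely.geometry import LineString, mapping, shape

from .aggregate import Block
from .gvi import classify_gvi
from .network import SampleSite, StreetSegment, aeqd_to_lonlat

__all__ = [
    "read_lines_geojson",
    "write_segments_geojson",
    "write_sites_csv",
    "write_sites_geojson",
    "write_blocks_geojson",
]


def _dump_geojson(features: list[dict], path: Path) -> None:
    doc = {"type": "FeatureCollection", "features": features}
    path.write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")) + "\n")


def read_lines_geojson(
    path: str | Path,
    class_field: str = "class",
    bridge_field: str | None = None,
    default_class: int = 3,
) -> list[StreetSegment]:
    """Load street centerlines from a GeoJSON LineString layer."""
    doc = json.loads(Path(path).read_text())
    segments: list[StreetSegment] = []
    for k, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        geoms = geom.geoms if geom.geom_type == "MultiLineString" else [geom]
        for g, line in enumerate(geoms):
            if not isinstance(line, LineString) or line.length == 0:
                continue
            sid = str(props.get("id", k))
            if len(list(geoms)) > 1:
                sid = f"{sid}_{g}"
            attrs = {}
            if bridge_field is not None and bridge_field in props:
                attrs["bridge"] = bool(props[bridge_field])
            segments.append(
                StreetSegment(
                    id=sid,
                    geometry=line,
                    road_class=int(props.get(class_field, default_class)),
                    attributes=attrs,
                )
            )
    return segments


def write_segments_geojson(
    segments: Sequence[StreetSegment],
    path: str | Path,
    stats: pd.DataFrame | None = None,
) -> Path:
    """Write segments (optionally with per-segment GVI stats) as GeoJSON."""
    by_id = {}
    if stats is not None:
        by_id = stats.set_index("segment_id").to_dict("index")
    features = []
    for s in segments:
        props: dict = {"id": s.id, "class": s.road_class, "length_m": round(s.length, 3)}
        if s.id in by_id:
            row = by_id[s.id]
            props.update(
                n_sites=int(row["n_sites"]),
                gvi_mean=round(float(row["mean_gvi"]), 6),
                gvi_std=round(float(row["std_gvi"]), 6),
                sites_per_km=round(float(row["sites_per_km"]), 3),
                category=classify_gvi(min(max(float(row["mean_gvi"]), 0.0), 1.0)),
            )
        features.append(
            {"type": "Feature", "geometry": mapping(s.geometry), "properties": props}
        )
    path = Path(path)
    _dump_geojson(features, path)
    return path


def write_sites_csv(
    sites: Sequence[SampleSite],
    path: str | Path,
    center_lonlat: tuple[float, float] | None = None,
) -> Path:
    """Write sample sites as CSV (ids, coordinates, chainage, headings).

    When the projection center is known, lon/lat columns are included by
    inverting the local azimuthal-equidistant projection.
    """
    rows = []
    for s in sites:
        front, back, left, right = s.headings
        row = {
            "site_id": s.id,
            "segment_id": s.segment_id,
            "x": round(s.x, 3),
            "y": round(s.y, 3),
            "chainage": round(s.chainage, 3),
            "azimuth": round(s.forward_azimuth, 3),
            "h_front": round(front, 3),
            "h_back": round(back, 3),
            "h_left": round(left, 3),
            "h_right": round(right, 3),
        }
        if center_lonlat is not None:
            lon, lat = aeqd_to_lonlat(s.x, s.y, center_lonlat)
            row["lon"] = round(float(lon), 8)
            row["lat"] = round(float(lat), 8)
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_sites_geojson(sites: Sequence[SampleSite], path: str | Path) -> Path:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [round(s.x, 3), round(s.y, 3)]},
            "properties": {
                "site_id": s.id,
                "segment_id": s.segment_id,
                "chainage": round(s.chainage, 3),
                "azimuth": round(s.forward_azimuth, 3),
            },
        }
        for s in sites
    ]
    path = Path(path)
    _dump_geojson(features, path)
    return path


def write_blocks_geojson(blocks: Sequence[Block], path: str | Path) -> Path:
    features = []
    for b in blocks:
        props = {
            "block_id": b.block_id,
            "area_ha": round(b.area_ha, 6),
            "n_sites": b.n_sites,
            "sites_per_ha": round(b.sites_per_ha, 6),
        }
        if b.mean_gvi is not None:
            props["gvi_mean"] = round(b.mean_gvi, 6)
            props["category"] = classify_gvi(min(max(b.mean_gvi, 0.0), 1.0))
        features.append(
            {"type": "Feature", "geometry": mapping(b.polygon), "properties": props}
        )
    path = Path(path)
    _dump_geojson(features, path)
    return path
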