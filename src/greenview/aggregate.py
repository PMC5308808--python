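"""Aggregation of site GVIs to street segments and urban blocks.

A block is the contiguous polygon left when the street space — the union of
class-dependent buffers (half-widths between 2 and 30 m) around the street
network — is subtracted from the study area.  Sites are assigned to their
nearest block and block GVI is the mean of the assigned sites.  Density
filters keep only units sampled densely enough to be meaningful: street
segments with more than 13 locations per km, blocks larger than 1 ha with
more than 1 location per ha.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union

from .network import StreetSegment, StudyArea

__all__ = [
    "BufferScheme",
    "Block",
    "aggregate_segments",
    "delineate_blocks",
    "assign_sites_to_blocks",
    "filter_units",
]

logger = logging.getLogger(__name__)

MIN_HALF_WIDTH, MAX_HALF_WIDTH = 2.0, 30.0
SEGMENT_MIN_SITES_PER_KM = 13.0
BLOCK_MIN_AREA_HA = 1.0
BLOCK_MIN_SITES_PER_HA = 1.0


@dataclass(frozen=True)
class BufferScheme:
    """Street half-width in meters per road class."""

    widths: Mapping[int, float]

    def __post_init__(self) -> None:
        for cls, w in self.widths.items():
            if not (MIN_HALF_WIDTH <= w <= MAX_HALF_WIDTH):
                raise ValueError(
                    f"half-width {w} for class {cls} outside "
                    f"[{MIN_HALF_WIDTH}, {MAX_HALF_WIDTH}] m"
                )

    def width_for(self, road_class: int) -> float:
        if road_class not in self.widths:
            raise KeyError(f"no buffer half-width for road class {road_class}")
        return self.widths[road_class]

    @classmethod
    def linear(cls, classes: Sequence[int]) -> "BufferScheme":
        """Half-widths spanning [2, 30] m linearly: widest for the highest
        road grade (lowest class number), narrowest for lanes."""
        uniq = sorted(set(classes))
        if len(uniq) == 1:
            return cls({uniq[0]: (MIN_HALF_WIDTH + MAX_HALF_WIDTH) / 2})
        span = MAX_HALF_WIDTH - MIN_HALF_WIDTH
        return cls(
            {
                c: MAX_HALF_WIDTH - span * k / (len(uniq) - 1)
                for k, c in enumerate(uniq)
            }
        )


@dataclass
class Block:
    """A street-bounded polygon with aggregated greenery statistics."""

    block_id: str
    polygon: Polygon
    area_ha: float
    n_sites: int = 0
    mean_gvi: float | None = None
    sites_per_ha: float = 0.0


def aggregate_segments(
    site_gvis: pd.DataFrame, segment_lengths: Mapping[str, float]
) -> pd.DataFrame:
    """Per-segment GVI statistics from site GVIs.

    ``site_gvis`` needs columns ``segment_id`` and ``gvi``.  Returns one row
    per segment with at least one site: n_sites, mean/std (population sd)
    GVI, length_m and sites_per_km.
    """
    if not {"segment_id", "gvi"} <= set(site_gvis.columns):
        raise ValueError("site_gvis needs columns segment_id and gvi")
    grouped = site_gvis.groupby("segment_id")["gvi"]
    out = pd.DataFrame(
        {
            "n_sites": grouped.size(),
            "mean_gvi": grouped.mean(),
            "std_gvi": grouped.std(ddof=0),
        }
    ).reset_index()
    out["length_m"] = out["segment_id"].map(segment_lengths)
    if out["length_m"].isna().any():
        missing = out.loc[out["length_m"].isna(), "segment_id"].tolist()
        raise KeyError(f"no length known for segments {missing[:5]}")
    out["sites_per_km"] = out["n_sites"] / (out["length_m"] / 1000.0)
    return out


def delineate_blocks(
    segments: Sequence[StreetSegment],
    scheme: BufferScheme,
    study_area: StudyArea | Polygon | None = None,
) -> list[Block]:
    """Subtract the buffered street space from the study area.

    The connected components of the remainder are the blocks.  When no
    study area is given, the convex hull of the network serves as the
    extent.  Block ids are assigned deterministically by the lower-left
    corner of each polygon's bounding box.
    """
    if not segments:
        warnings.warn("empty street network: the study area is a single block")
        if study_area is None:
            return []
        poly = study_area.polygon() if isinstance(study_area, StudyArea) else study_area
        return [Block("B0000", poly, poly.area / 1e4)]
    buffers = [
        s.geometry.buffer(scheme.width_for(s.road_class)) for s in segments
    ]
    street_space = unary_union(buffers)
    if study_area is None:
        extent = unary_union([s.geometry for s in segments]).convex_hull
    elif isinstance(study_area, StudyArea):
        extent = study_area.polygon()
    else:
        extent = study_area
    remainder = extent.difference(street_space)
    if remainder.is_empty:
        warnings.warn("street space covers the whole study area; no blocks")
        return []
    if isinstance(remainder, Polygon):
        polys = [remainder]
    elif isinstance(remainder, MultiPolygon):
        polys = list(remainder.geoms)
    else:
        polys = [g for g in remainder.geoms if isinstance(g, Polygon)]
    polys = [p for p in polys if p.area > 0]
    polys.sort(key=lambda p: (round(p.bounds[1], 6), round(p.bounds[0], 6)))
    return [
        Block(f"B{k:04d}", p, p.area / 1e4) for k, p in enumerate(polys)
    ]


def assign_sites_to_blocks(
    sites: pd.DataFrame, blocks: Sequence[Block]
) -> tuple[list[Block], pd.Series]:
    """Assign every site to its nearest block and average GVI per block.

    ``sites`` needs columns x, y, gvi.  Distance is the Euclidean distance
    to the block polygon (0 inside); ties go to the smallest block_id.
    Returns the updated blocks and the per-site block assignment.
    """
    if not blocks:
        raise ValueError("no blocks to assign sites to")
    if not {"x", "y", "gvi"} <= set(sites.columns):
        raise ValueError("sites needs columns x, y and gvi")
    ordered = sorted(blocks, key=lambda b: b.block_id)
    assignment = []
    for x, y in zip(sites["x"], sites["y"]):
        p = Point(x, y)
        dists = np.array([b.polygon.distance(p) for b in ordered])
        best = float(dists.min())
        # first block (smallest id) within tolerance of the minimum
        idx = int(np.nonzero(dists <= best + 1e-9)[0][0])
        assignment.append(ordered[idx].block_id)
    assignment = pd.Series(assignment, index=sites.index, name="block_id")
    for b in ordered:
        sel = assignment == b.block_id
        b.n_sites = int(sel.sum())
        b.mean_gvi = float(sites.loc[sel, "gvi"].mean()) if b.n_sites else None
        b.sites_per_ha = b.n_sites / b.area_ha if b.area_ha > 0 else 0.0
    return ordered, assignment


def filter_units(
    segment_stats: pd.DataFrame,
    blocks: Sequence[Block],
    segment_min_per_km: float = SEGMENT_MIN_SITES_PER_KM,
    block_min_area_ha: float = BLOCK_MIN_AREA_HA,
    block_min_per_ha: float = BLOCK_MIN_SITES_PER_HA,
) -> tuple[pd.DataFrame, list[Block]]:
    """Density filters: keep segments with more than ``segment_min_per_km``
    locations per km, blocks larger than ``block_min_area_ha`` with more
    than ``block_min_per_ha`` locations per ha (strict inequalities)."""
    keep_seg = segment_stats[segment_stats["sites_per_km"] > segment_min_per_km]
    keep_blocks = [
        b
        for b in blocks
        if b.area_ha > block_min_area_ha and b.sites_per_ha > block_min_per_ha
    ]
    logger.info(
        "filter_units: kept %d/%d segments, %d/%d blocks",
        len(keep_seg),
        len(segment_stats),
        len(keep_blocks),
        len(blocks),
    )
    return keep_seg.reset_index(drop=True), keep_blocks
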