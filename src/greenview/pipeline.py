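"""Resumable pipeline: preprocess -> sample -> fetch -> gvi -> aggregate -> citystats.

Each stage reads the previous stage's files from the run directory, writes
its own outputs under fixed names, and records completion plus SHA-256
digests in ``manifest.json``.  Re-running a completed stage is a no-op
unless forced; a stage refuses to run when its upstream outputs changed
since the upstream stage was recorded (stale digests) or the upstream stage
never ran.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import aggregate as agg
from . import citystats as cs
from . import io as gio
from . import network as net
from . import provider as prov
from .gvi import GreenRange, classify_gvi, hue_histogram, picture_gvi, site_gvi
from .synthetic import NetworkSpec, make_street_grid

__all__ = ["RunConfig", "Pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("preprocess", "sample", "fetch", "gvi", "aggregate", "citystats")

#: files each stage consumes from the run directory
_STAGE_INPUTS: dict[str, tuple[str, ...]] = {
    "preprocess": (),
    "sample": ("network.geojson",),
    "fetch": ("sites.csv",),
    "gvi": ("inventory.csv",),
    "aggregate": ("sites_gvi.csv", "network.geojson"),
    "citystats": ("sites_gvi.csv",),
}


@dataclass
class RunConfig:
    """All knobs of one pipeline run; loadable from YAML."""

    seed: int = 0
    # study area (projected meters unless lonlat_center is given)
    center: tuple[float, float] | None = None
    lonlat_center: tuple[float, float] | None = None
    radius: float = 3000.0
    # network source
    network_source: str = "synthetic"  # synthetic | file
    network_path: str | None = None
    class_field: str = "class"
    bridge_field: str | None = None
    network_lonlat: bool = False
    synthetic_network: dict = field(default_factory=dict)
    # preprocessing
    merge_distance: float = 25.0
    excluded_classes: tuple[int, ...] = (1,)
    dangle_threshold: float = 100.0
    clip: bool = False
    # sampling
    interval: float = 50.0
    # provider
    provider_kind: str = "mock"  # mock | local | none
    search_radius: float = 50.0
    image_width: int = 960
    image_height: int = 640
    quota: int = prov.DEFAULT_QUOTA
    local_root: str | None = None
    mock_coverage: float = 0.95
    # GVI
    green_lo: int = 60
    green_hi: int = 180
    min_saturation: float = 0.0  # reserved sensitivity knobs
    min_value: float = 0.0
    # aggregation
    buffer_widths: dict[int, float] | None = None
    segment_min_per_km: float = agg.SEGMENT_MIN_SITES_PER_KM
    block_min_area_ha: float = agg.BLOCK_MIN_AREA_HA
    block_min_per_ha: float = agg.BLOCK_MIN_SITES_PER_HA
    # citystats
    locations_csv: str | None = None
    models: tuple[int, ...] = (1, 2, 3)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("center", "lonlat_center", "excluded_classes", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "buffer_widths" in raw and raw["buffer_widths"] is not None:
            raw["buffer_widths"] = {int(k): float(v) for k, v in raw["buffer_widths"].items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=list))

    @property
    def green_range(self) -> GreenRange:
        return GreenRange(self.green_lo, self.green_hi)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class StaleInputError(RuntimeError):
    """Upstream outputs changed after their stage was recorded."""


class Pipeline:
    def __init__(self, config: RunConfig, run_dir: str | Path):
        self.config = config
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.run_dir / "manifest.json"

    # -- manifest -----------------------------------------------------------
    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            return json.loads(self.manifest_path.read_text())
        return {"config": self.config.to_dict(), "stages": {}}

    def _record(self, manifest: dict, stage: str, outputs: list[Path], counts: Mapping) -> None:
        manifest["stages"][stage] = {
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "inputs": {
                name: _sha256(self.run_dir / name)
                for name in _STAGE_INPUTS[stage]
                if (self.run_dir / name).exists()
            },
            "outputs": {p.name: _sha256(p) for p in outputs},
            "counts": dict(counts),
        }
        self.manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    def _check_upstream(self, manifest: dict, stage: str) -> None:
        idx = STAGES.index(stage)
        if idx == 0:
            return
        upstream = STAGES[idx - 1]
        needed = _STAGE_INPUTS[stage]
        up_rec = manifest["stages"].get(upstream)
        if up_rec is None:
            missing = [n for n in needed if not (self.run_dir / n).exists()]
            if missing:
                raise RuntimeError(
                    f"stage '{stage}' needs outputs of '{upstream}' "
                    f"(missing {missing}); run it first or supply the files"
                )
            return  # inputs supplied directly
        for name in needed:
            recorded = up_rec["outputs"].get(name)
            current = self.run_dir / name
            if recorded is not None and current.exists() and _sha256(current) != recorded:
                raise StaleInputError(
                    f"'{name}' changed since stage '{upstream}' ran; "
                    f"re-run '{upstream}' (or --force it) before '{stage}'"
                )

    def run_stage(self, stage: str, force: bool = False) -> dict:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        manifest = self._load_manifest()
        rec = manifest["stages"].get(stage)
        if rec is not None and not force:
            intact = all(
                (self.run_dir / n).exists() and _sha256(self.run_dir / n) == h
                for n, h in rec["outputs"].items()
            )
            if intact:
                logger.info("stage %s already complete; skipping (use force to re-run)", stage)
                return rec
        self._check_upstream(manifest, stage)
        counts, outputs = getattr(self, f"_stage_{stage}")()
        self._record(manifest, stage, outputs, counts)
        return manifest["stages"][stage]

    def run_all(self, force: bool = False) -> dict:
        for stage in STAGES:
            self.run_stage(stage, force=force)
        return self._load_manifest()

    # -- stages -------------------------------------------------------------
    def _study_area(self) -> net.StudyArea | None:
        c = self.config
        if c.lonlat_center is not None:
            return net.StudyArea((0.0, 0.0), c.radius)  # projection is centered there
        if c.center is not None:
            return net.StudyArea(tuple(c.center), c.radius)
        return None

    def _stage_preprocess(self):
        c = self.config
        if c.network_source == "synthetic":
            spec = NetworkSpec(**{"seed": c.seed, **c.synthetic_network})
            segments = make_street_grid(spec)
        elif c.network_source == "file":
            if not c.network_path:
                raise ValueError("network_source=file requires network_path")
            segments = gio.read_lines_geojson(
                c.network_path, class_field=c.class_field, bridge_field=c.bridge_field
            )
            if c.network_lonlat:
                if c.lonlat_center is None:
                    raise ValueError("lon/lat input requires lonlat_center")
                segments = [
                    net.StreetSegment(
                        s.id,
                        type(s.geometry)(
                            list(
                                zip(
                                    *net.lonlat_to_aeqd(
                                        np.array([p[0] for p in s.geometry.coords]),
                                        np.array([p[1] for p in s.geometry.coords]),
                                        c.lonlat_center,
                                    )
                                )
                            )
                        ),
                        s.road_class,
                        s.attributes,
                    )
                    for s in segments
                ]
        else:
            raise ValueError(f"unknown network_source {c.network_source!r}")
        n_raw = len(segments)
        segments = net.merge_divided_roads(segments, c.merge_distance)
        segments = net.remove_unsuitable(segments, c.excluded_classes)
        segments = net.enforce_topology(segments, c.dangle_threshold)
        area = self._study_area()
        if c.clip and area is not None:
            segments = net.clip_to_study_area(segments, area)
        out = gio.write_segments_geojson(segments, self.run_dir / "network.geojson")
        return {"segments_in": n_raw, "segments_out": len(segments)}, [out]

    def _stage_sample(self):
        c = self.config
        segments = gio.read_lines_geojson(self.run_dir / "network.geojson")
        sites = net.sample_network(segments, c.interval)
        out_csv = gio.write_sites_csv(
            sites, self.run_dir / "sites.csv", center_lonlat=c.lonlat_center
        )
        out_geo = gio.write_sites_geojson(sites, self.run_dir / "sites.geojson")
        return {"segments": len(segments), "sites": len(sites)}, [out_csv, out_geo]

    def _sites_from_csv(self) -> list[net.SampleSite]:
        df = pd.read_csv(self.run_dir / "sites.csv")
        return [
            net.SampleSite(
                id=str(r.site_id),
                segment_id=str(r.segment_id),
                x=float(r.x),
                y=float(r.y),
                chainage=float(r.chainage),
                forward_azimuth=float(r.azimuth),
            )
            for r in df.itertuples()
        ]

    def _make_provider(self, sites: list[net.SampleSite]) -> prov.StreetViewProvider:
        c = self.config
        if c.provider_kind == "mock":
            rng = np.random.default_rng(c.seed)
            panos = []
            for k, s in enumerate(sites):
                if rng.random() < c.mock_coverage:
                    dx, dy = rng.uniform(-5, 5, 2)
                    panos.append((f"p{k:05d}", (s.x + dx, s.y + dy)))
            return prov.MockProvider(panos, seed=c.seed, quota=c.quota)
        if c.provider_kind == "local":
            if not c.local_root:
                raise ValueError("provider_kind=local requires local_root")
            return prov.LocalDirectoryProvider(c.local_root, quota=c.quota)
        raise ValueError(f"unknown provider kind {c.provider_kind!r}")

    def _stage_fetch(self):
        c = self.config
        sites = self._sites_from_csv()
        if c.provider_kind == "none":
            # bypass: a pre-populated image directory + inventory must exist
            inv_path = self.run_dir / "inventory.csv"
            if not inv_path.exists():
                raise RuntimeError(
                    "provider_kind=none requires a pre-populated inventory.csv"
                )
            inv = pd.read_csv(inv_path)
            return {"sites": len(sites), "rows": len(inv)}, [inv_path]
        provider = self._make_provider(sites)
        inv = prov.build_inventory(
            sites,
            provider,
            search_radius=c.search_radius,
            image_dir=self.run_dir / "images",
            width=c.image_width,
            height=c.image_height,
        )
        out = self.run_dir / "inventory.csv"
        inv.to_csv(out, index=False)
        ok = int((inv["status"] == "ok").sum())
        return {
            "sites": len(sites),
            "rows": len(inv),
            "images_ok": ok,
            "images_missing": len(inv) - ok,
        }, [out]

    def _stage_gvi(self):
        c = self.config
        inv = pd.read_csv(self.run_dir / "inventory.csv", keep_default_na=False)
        green = c.green_range
        gvis: list[float | None] = []
        counted: list[int | None] = []
        for r in inv.itertuples():
            if r.status != "ok" or not r.file_name:
                gvis.append(None)
                counted.append(None)
                continue
            with Image.open(self.run_dir / "images" / r.file_name) as im:
                arr = np.asarray(im.convert("RGB"))
            hist = hue_histogram(arr)
            gvis.append(picture_gvi(hist, green))
            counted.append(hist.counted_pixels)
        inv["gvi"] = gvis
        inv["counted_pixels"] = counted
        out_inv = self.run_dir / "gvi.csv"
        inv.to_csv(out_inv, index=False)

        ok = inv[inv["status"] == "ok"]
        rows = []
        n_excluded = 0
        for (sid, seg), grp in ok.groupby(["site_id", "segment_id"], sort=True):
            vals = grp["gvi"].dropna().tolist()
            if not vals:
                n_excluded += 1
                continue
            rows.append(
                {
                    "site_id": sid,
                    "segment_id": seg,
                    "x": grp["x"].iloc[0],
                    "y": grp["y"].iloc[0],
                    "n_images": len(vals),
                    "gvi": round(site_gvi(vals), 9),
                }
            )
        # sites with zero usable images are excluded and counted
        all_sites = inv["site_id"].nunique()
        sites_df = pd.DataFrame(
            rows, columns=["site_id", "segment_id", "x", "y", "n_images", "gvi"]
        )
        out_sites = self.run_dir / "sites_gvi.csv"
        sites_df.to_csv(out_sites, index=False)
        return {
            "images_scored": int(ok["gvi"].notna().sum()),
            "sites_with_gvi": len(sites_df),
            "sites_excluded": all_sites - len(sites_df),
        }, [out_inv, out_sites]

    def _stage_aggregate(self):
        c = self.config
        sites = pd.read_csv(self.run_dir / "sites_gvi.csv")
        segments = gio.read_lines_geojson(self.run_dir / "network.geojson")
        lengths = {s.id: s.length for s in segments}
        sites["segment_id"] = sites["segment_id"].astype(str)
        seg_stats = agg.aggregate_segments(sites, lengths)
        if c.buffer_widths:
            scheme = agg.BufferScheme(c.buffer_widths)
        else:
            scheme = agg.BufferScheme.linear([s.road_class for s in segments])
        blocks = agg.delineate_blocks(segments, scheme, self._study_area() if c.clip else None)
        if blocks:
            blocks, _ = agg.assign_sites_to_blocks(sites, blocks)
        kept_seg, kept_blocks = agg.filter_units(
            seg_stats,
            blocks,
            segment_min_per_km=c.segment_min_per_km,
            block_min_area_ha=c.block_min_area_ha,
            block_min_per_ha=c.block_min_per_ha,
        )
        out_seg_csv = self.run_dir / "segments.csv"
        seg_stats.to_csv(out_seg_csv, index=False)
        out_seg = gio.write_segments_geojson(
            segments, self.run_dir / "segments.geojson", stats=seg_stats
        )
        out_blocks = gio.write_blocks_geojson(blocks, self.run_dir / "blocks.geojson")
        return {
            "segments_with_sites": len(seg_stats),
            "segments_kept": len(kept_seg),
            "blocks": len(blocks),
            "blocks_kept": len(kept_blocks),
        }, [out_seg_csv, out_seg, out_blocks]

    def _stage_citystats(self):
        c = self.config
        sites = pd.read_csv(self.run_dir / "sites_gvi.csv")
        mean, std = cs.summarize_city(sites["gvi"].to_numpy())
        cats = sites["gvi"].clip(0, 1).map(classify_gvi).value_counts()
        summary = pd.DataFrame(
            [
                {
                    "n_sites": len(sites),
                    "mean_gvi": round(mean, 6),
                    "std_gvi": round(std, 6),
                    **{
                        label: int(cats.get(label, 0))
                        for label in ("not_green", "somewhat_green", "green", "very_green")
                    },
                }
            ]
        )
        out_summary = self.run_dir / "city_summary.csv"
        summary.to_csv(out_summary, index=False)
        outputs = [out_summary]
        counts = {"sites": len(sites)}
        if c.locations_csv:
            records = pd.read_csv(c.locations_csv)
            rows = []
            for m in c.models:
                res = cs.fit_location_models(records, m)
                for var in res.coefficients.index:
                    rows.append(
                        {
                            "model": res.model_id,
                            "variable": var,
                            "coefficient": round(float(res.coefficients[var]), 6),
                            "p_value": round(float(res.pvalues[var]), 6),
                            "adj_r2": round(res.adj_r2, 6),
                            "n": res.n,
                        }
                    )
            models = pd.DataFrame(rows)
            out_models = self.run_dir / "models.csv"
            models.to_csv(out_models, index=False)
            outputs.append(out_models)
            counts["model_rows"] = len(models)
        return counts, outputs
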