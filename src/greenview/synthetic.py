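"""Synthetic fixtures with known ground truth.

Three generators stand in for the data a real deployment would acquire:

* :func:`make_scene` — street-level photographs with a known per-pixel
  vegetation mask: green-hued canopy blobs over non-green clutter (sky,
  facades, achromatic road surface), with multiplicative illumination
  jitter applied to the HSV value channel only, so the hue ground truth
  survives lighting variation.
* :func:`make_street_grid` — planar street grids with configurable dual
  carriageways, dangling stubs and pseudo-nodes, the pathologies the
  network-preprocessing stage must repair.
* :func:`make_city_panel` — a multi-city panel of location records whose
  GVI response follows a known standardized linear model, for exercising
  the regression machinery with recoverable coefficients.

Every generator is deterministic given its spec (which embeds a seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from shapely.geometry import LineString
from skimage import color

from .network import StreetSegment

__all__ = [
    "SceneSpec",
    "NetworkSpec",
    "PanelSpec",
    "PANEL_VARIABLES",
    "make_scene",
    "make_street_grid",
    "make_city_panel",
    "write_scene",
    "write_panel_csv",
]

# Hue-quantisation guard: keeping hues >= this many degrees away from the
# band edges, with chroma floors below, guarantees the 8-bit RGB round trip
# cannot move a pixel across the green/non-green boundary.
_HUE_MARGIN_DEG = 4.0
_GREEN_SAT = (0.65, 0.95)
_GREEN_VAL = (0.55, 0.90)
_VAL_FLOOR = 0.35  # after jitter; keeps chroma high enough for stable hue


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic street scene."""

    width: int = 960
    height: int = 640
    green_fraction: float = 0.3
    green_hue_band: tuple[float, float] = (70.0, 170.0)
    #: (lo_deg, hi_deg, weight) chromatic clutter bands, disjoint from [60,180],
    #: plus an implicit achromatic (gray road/building) component.
    clutter_bands: tuple[tuple[float, float, float], ...] = (
        (195.0, 250.0, 0.35),  # sky
        (15.0, 50.0, 0.25),  # brick / facades
    )
    achromatic_weight: float = 0.40
    illumination_jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.green_fraction <= 1.0):
            raise ValueError("green_fraction must be in [0, 1]")
        lo, hi = self.green_hue_band
        if not (60.0 < lo < hi < 180.0):
            raise ValueError("green_hue_band must lie strictly inside (60, 180)")
        for blo, bhi, w in self.clutter_bands:
            if not (0.0 <= blo < bhi <= 360.0) or w < 0:
                raise ValueError(f"bad clutter band ({blo}, {bhi}, {w})")
            if bhi > 60.0 - _HUE_MARGIN_DEG and blo < 180.0 + _HUE_MARGIN_DEG:
                raise ValueError("clutter bands must stay clear of the green range")
        if self.illumination_jitter < 0:
            raise ValueError("illumination_jitter must be >= 0")
        if self.width < 1 or self.height < 1:
            raise ValueError("scene must have at least one pixel")


class SceneGeometryError(ValueError):
    """Requested green fraction unreachable on the integer pixel grid."""

    def __init__(self, requested: float, achievable: float):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"green_fraction {requested} unreachable; nearest achievable "
            f"fraction is {achievable}"
        )


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a scene and its vegetation mask.

    Returns ``(image, mask)``: an (H, W, 3) uint8 RGB image and an (H, W)
    boolean mask that marks exactly the pixels drawn from the green hue
    band.  The mask's true fraction matches ``spec.green_fraction`` to
    within half a pixel (and always within 0.01 for realistic sizes).

    Canopy pixels form coherent blobs: a smoothed Gaussian random field is
    thresholded at the quantile that yields the exact target pixel count.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    n = h * w
    n_green = int(round(spec.green_fraction * n))
    achievable = n_green / n
    if abs(achievable - spec.green_fraction) > 0.01:
        raise SceneGeometryError(spec.green_fraction, achievable)

    # Coherent canopy field: smoothed noise, synthesised at reduced
    # resolution for large scenes (the threshold step below keeps the green
    # pixel count exact regardless).
    sigma = max(2.0, min(h, w) / 10.0)
    scale = 8 if min(h, w) >= 64 else 1
    hs, ws = -(-h // scale) + 3, -(-w // scale) + 3
    lo_res = ndimage.gaussian_filter(
        rng.standard_normal((hs, ws)), sigma=sigma / scale
    )
    fld = ndimage.zoom(lo_res, scale, order=3)[:h, :w] if scale > 1 else lo_res[:h, :w]
    order = np.argsort(fld, axis=None)  # float field: ties essentially impossible
    mask = np.zeros(n, dtype=bool)
    if n_green > 0:
        mask[order[-n_green:]] = True
    mask = mask.reshape(h, w)

    hue = np.empty((h, w), dtype=float)
    sat = np.empty((h, w), dtype=float)
    val = np.empty((h, w), dtype=float)

    glo = spec.green_hue_band[0] + min(_HUE_MARGIN_DEG, 0.25 * np.ptp(spec.green_hue_band))
    ghi = spec.green_hue_band[1] - min(_HUE_MARGIN_DEG, 0.25 * np.ptp(spec.green_hue_band))
    hue[mask] = rng.uniform(glo, ghi, size=int(n_green))
    sat[mask] = rng.uniform(*_GREEN_SAT, size=int(n_green))
    val[mask] = rng.uniform(*_GREEN_VAL, size=int(n_green))

    n_bg = n - n_green
    if n_bg > 0:
        weights = np.array([wt for *_, wt in spec.clutter_bands] + [spec.achromatic_weight])
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
        weights = weights / weights.sum()
        choice = rng.choice(len(weights), size=n_bg, p=weights)
        bh = np.empty(n_bg)
        bs = np.empty(n_bg)
        bv = np.empty(n_bg)
        for k, (blo, bhi, _) in enumerate(spec.clutter_bands):
            sel = choice == k
            bh[sel] = rng.uniform(blo, bhi, size=int(sel.sum()))
            bs[sel] = rng.uniform(0.35, 0.9, size=int(sel.sum()))
            bv[sel] = rng.uniform(0.45, 1.0, size=int(sel.sum()))
        ach = choice == len(spec.clutter_bands)
        bh[ach] = 0.0
        bs[ach] = 0.0
        bv[ach] = rng.uniform(0.15, 0.95, size=int(ach.sum()))
        hue[~mask] = bh
        sat[~mask] = bs
        val[~mask] = bv

    if spec.illumination_jitter > 0:
        val = val * (1.0 + spec.illumination_jitter * rng.standard_normal((h, w)))
    # Chromatic pixels keep a value floor so quantisation cannot shift hue
    # across the band edge; achromatic pixels may go fully dark.
    chromatic = sat > 0
    val[chromatic] = np.clip(val[chromatic], _VAL_FLOOR, 1.0)
    val[~chromatic] = np.clip(val[~chromatic], 0.0, 1.0)

    hsv = np.stack([hue / 360.0, sat, val], axis=-1)
    image = np.round(color.hsv2rgb(hsv) * 255.0).astype(np.uint8)
    return image, mask


def write_scene(image: np.ndarray, mask: np.ndarray, path: str | Path) -> tuple[Path, Path]:
    """Write a scene as PNG plus a sidecar 0/255 single-channel mask PNG."""
    path = Path(path)
    mask_path = path.with_name(path.stem + "_mask.png")
    Image.fromarray(image, mode="RGB").save(path)
    Image.fromarray((mask.astype(np.uint8) * 255), mode="L").save(mask_path)
    return path, mask_path


# ---------------------------------------------------------------------------
# Street grids


@dataclass(frozen=True)
class NetworkSpec:
    """A rectangular street grid with optional pathologies.

    ``grid_rows``/``grid_cols`` count intersection nodes; edges join
    neighbouring nodes, so a clean grid has ``2*r*c - r - c`` segments.
    """

    grid_rows: int = 3
    grid_cols: int = 3
    spacing: float = 200.0
    dual_carriageway_fraction: float = 0.0
    carriageway_offset: float = 20.0
    dangle_count: int = 0
    dangle_length: float = 40.0
    pseudo_node_count: int = 0
    road_class: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise ValueError("grid must be at least 2x2 nodes")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not (0.0 <= self.dual_carriageway_fraction <= 1.0):
            raise ValueError("dual_carriageway_fraction must be in [0, 1]")
        if self.carriageway_offset >= self.spacing / 2:
            raise ValueError("carriageway offset must be below spacing/2")
        if self.dangle_length >= self.spacing:
            raise ValueError("dangle_length must be below spacing")


def make_street_grid(spec: NetworkSpec) -> list[StreetSegment]:
    """Emit the street segments of a grid per ``spec``.

    Dual carriageways replace a chosen edge by two parallel lines of the
    same class offset by ``carriageway_offset``; dangles are short degree-1
    stubs poking into a block from a grid node; pseudo-nodes split an edge
    into two collinear halves sharing a degree-2 node.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.spacing
    edges: list[tuple[str, tuple[float, float], tuple[float, float]]] = []
    for i in range(spec.grid_rows):
        for j in range(spec.grid_cols - 1):
            edges.append((f"h{i}_{j}", (j * s, i * s), ((j + 1) * s, i * s)))
    for i in range(spec.grid_rows - 1):
        for j in range(spec.grid_cols):
            edges.append((f"v{i}_{j}", (j * s, i * s), (j * s, (i + 1) * s)))

    n_dual = int(round(spec.dual_carriageway_fraction * len(edges)))
    dual_idx = set(rng.choice(len(edges), size=n_dual, replace=False).tolist())
    pseudo_pool = [k for k in range(len(edges)) if k not in dual_idx]
    if spec.pseudo_node_count > len(pseudo_pool):
        raise ValueError("more pseudo-nodes requested than available edges")
    pseudo_idx = set(
        rng.choice(pseudo_pool, size=spec.pseudo_node_count, replace=False).tolist()
    )

    segments: list[StreetSegment] = []
    for k, (eid, a, b) in enumerate(edges):
        if k in dual_idx:
            ax, ay = a
            bx, by = b
            dx, dy = bx - ax, by - ay
            length = float(np.hypot(dx, dy))
            nx_, ny_ = -dy / length, dx / length  # unit normal
            off = spec.carriageway_offset / 2.0
            for side, sgn in (("a", 1.0), ("b", -1.0)):
                line = LineString(
                    [
                        (ax + sgn * off * nx_, ay + sgn * off * ny_),
                        (bx + sgn * off * nx_, by + sgn * off * ny_),
                    ]
                )
                segments.append(StreetSegment(f"{eid}_{side}", line, spec.road_class))
        elif k in pseudo_idx:
            mid = ((a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0)
            segments.append(StreetSegment(f"{eid}_s1", LineString([a, mid]), spec.road_class))
            segments.append(StreetSegment(f"{eid}_s2", LineString([mid, b]), spec.road_class))
        else:
            segments.append(StreetSegment(eid, LineString([a, b]), spec.road_class))

    # Dangles: stubs leaving an interior grid node diagonally into a block.
    interior = [
        (i, j)
        for i in range(spec.grid_rows)
        for j in range(spec.grid_cols)
        if 0 < i < spec.grid_rows - 1 or 0 < j < spec.grid_cols - 1
    ]
    if spec.dangle_count > len(interior):
        raise ValueError("more dangles requested than available nodes")
    picks = rng.choice(len(interior), size=spec.dangle_count, replace=False)
    for d, p in enumerate(picks):
        i, j = interior[int(p)]
        x0, y0 = j * s, i * s
        ang = np.deg2rad(45.0)
        tip = (x0 + spec.dangle_length * np.cos(ang), y0 + spec.dangle_length * np.sin(ang))
        segments.append(
            StreetSegment(f"dangle{d}", LineString([(x0, y0), tip]), spec.road_class)
        )
    return segments


# ---------------------------------------------------------------------------
# Regression panels

#: Location-level regression variables: two street-level predictors and the
#: city-level controls, in the order the models add them.
PANEL_VARIABLES = (
    "CENTER",
    "LENGTH",
    "SIZE",
    "LEVEL",
    "DENSITY",
    "ECONOMY",
    "ELEVATION",
    "WATER",
    "MIDDLE",
    "WEST",
)


@dataclass(frozen=True)
class PanelSpec:
    """A multi-city panel with a known standardized linear GVI response."""

    n_cities: int = 50
    sites_per_city: int = 100
    coefficients: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cities < 2:
            raise ValueError("need at least 2 cities")
        if self.sites_per_city < 1:
            raise ValueError("need at least 1 site per city")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.coefficients) - set(PANEL_VARIABLES)
        if unknown:
            raise ValueError(f"unknown panel variables: {sorted(unknown)}")


def make_city_panel(spec: PanelSpec) -> pd.DataFrame:
    """Generate location records with a known standardized effect structure.

    City covariates are drawn per city (administrative level, size, density,
    economy, elevation, water presence, region), site covariates per site
    (distance to center within the 3 km study disc; street length around the
    ~150 m national average).  All covariates are z-scored within the panel
    and the GVI response is their linear combination with the spec's
    standardized coefficients plus Gaussian noise.
    """
    n = spec.n_cities * spec.sites_per_city
    if n < len(PANEL_VARIABLES) + 2:
        raise ValueError(
            f"panel of {n} rows cannot support {len(PANEL_VARIABLES)} covariates"
        )
    rng = np.random.default_rng(spec.seed)
    level = rng.choice([1, 2, 3, 4], size=spec.n_cities, p=[0.03, 0.07, 0.1, 0.8])
    region = rng.choice(["east", "middle", "west"], size=spec.n_cities, p=[0.5, 0.25, 0.25])
    city = pd.DataFrame(
        {
            "LEVEL": level.astype(float),
            "SIZE": rng.lognormal(5.0, 0.8, spec.n_cities),
            "DENSITY": rng.lognormal(8.0, 0.6, spec.n_cities),
            "ECONOMY": rng.lognormal(6.0, 1.0, spec.n_cities),
            "ELEVATION": rng.gamma(2.0, 250.0, spec.n_cities),
            "WATER": rng.integers(0, 2, spec.n_cities).astype(float),
            "MIDDLE": (region == "middle").astype(float),
            "WEST": (region == "west").astype(float),
        }
    )
    city_idx = np.repeat(np.arange(spec.n_cities), spec.sites_per_city)
    df = city.iloc[city_idx].reset_index(drop=True)
    df.insert(0, "city_id", [f"c{c:03d}" for c in city_idx])
    df.insert(0, "site_id", [f"s{i:06d}" for i in range(n)])
    df["CENTER"] = rng.uniform(0.0, 3000.0, n)
    df["LENGTH"] = rng.lognormal(np.log(150.0), 0.6, n)
    df["LEVEL_RAW"] = df["LEVEL"].astype(int)  # kept for per-level subsetting

    z = pd.DataFrame(index=df.index)
    for v in PANEL_VARIABLES:
        col = df[v].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            z[v] = 0.0
        else:
            z[v] = (col - col.mean()) / sd
        df[v] = z[v]  # panel carries standardized covariates

    y = np.zeros(n)
    for v, beta in spec.coefficients.items():
        y += beta * z[v].to_numpy()
    y += spec.noise_sd * rng.standard_normal(n)
    df["GVI"] = y
    return df[["site_id", "city_id", "GVI", "LEVEL_RAW", *PANEL_VARIABLES]]


def write_panel_csv(panel: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    panel.to_csv(path, index=False)
    return path
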