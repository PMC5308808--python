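"""Street-view picture providers.

A provider answers two questions: *is there a panorama near this
coordinate?* (:meth:`find_pano`) and *give me the picture for this
panorama/heading* (:meth:`fetch_image`).  Three implementations share the
interface:

* :class:`MockProvider` — backed by the synthetic scene generator; fully
  deterministic, used by the test surfaces and the mock pipeline.
* :class:`LocalDirectoryProvider` — reads a pre-populated directory
  (``root/<pano_id>/<heading>.png`` plus an ``index.csv`` of coordinates).
* :class:`TencentProvider` — the live HTTP dialect (size/location/pano/
  heading/pitch/key parameters); it is never exercised in tests.

Image queries are charged against a per-key quota (default 100,000).
"""

from __future__ import annotations

import io
import urllib.error
import urllib.parse
import urllib.request
import zlib
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .network import SampleSite

__all__ = [
    "PanoQuery",
    "PanoRecord",
    "ProviderError",
    "QuotaExceededError",
    "AuthError",
    "ProviderUnreachableError",
    "StreetViewProvider",
    "MockProvider",
    "LocalDirectoryProvider",
    "TencentProvider",
    "build_inventory",
    "HEADING_LABELS",
]

HEADING_LABELS = ("front", "back", "left", "right")

DEFAULT_QUOTA = 100_000
MAX_WIDTH, MAX_HEIGHT = 960, 640


class ProviderError(RuntimeError):
    """Base class for provider failures."""


class QuotaExceededError(ProviderError):
    """The per-key query budget is exhausted."""


class AuthError(ProviderError):
    """The developer key was rejected."""


class ProviderUnreachableError(ProviderError):
    """Transient transport failure; retryable, distinct from 'no pano'."""


@dataclass(frozen=True)
class PanoQuery:
    """An image request in the provider dialect.

    Exactly one of ``pano_id`` / ``location`` identifies the panorama;
    ``heading`` is degrees clockwise from north, ``pitch`` the vertical
    angle in [-20, 90] (0 = horizontal).
    """

    width: int = MAX_WIDTH
    height: int = MAX_HEIGHT
    pano_id: str | None = None
    location: tuple[float, float] | None = None
    heading: float = 0.0
    pitch: float = 0.0
    key: str = ""

    def __post_init__(self) -> None:
        if (self.pano_id is None) == (self.location is None):
            raise ValueError("exactly one of pano_id / location must be set")
        if not (1 <= self.width <= MAX_WIDTH and 1 <= self.height <= MAX_HEIGHT):
            raise ValueError(f"size limited to {MAX_WIDTH}x{MAX_HEIGHT} pixels")
        if not (0.0 <= self.heading < 360.0):
            raise ValueError("heading must be in [0, 360)")
        if not (-20.0 <= self.pitch <= 90.0):
            raise ValueError("pitch must be in [-20, 90]")


@dataclass(frozen=True)
class PanoRecord:
    """Identity of a panorama returned by a place-ID lookup."""

    pano_id: str
    coordinate: tuple[float, float]
    capture_date: str | None = None  # not exposed by the live service

    def __post_init__(self) -> None:
        if not self.pano_id:
            raise ValueError("pano_id must be nonempty")


class StreetViewProvider(ABC):
    """Provider interface with client-side quota accounting."""

    def __init__(self, quota: int = DEFAULT_QUOTA, queries_used: int = 0):
        self.quota = quota
        self.queries_used = queries_used

    def _charge(self) -> None:
        if self.queries_used >= self.quota:
            raise QuotaExceededError(
                f"query budget of {self.quota} per key exhausted"
            )
        self.queries_used += 1

    @abstractmethod
    def find_pano(
        self, coordinate: tuple[float, float], search_radius: float = 50.0
    ) -> PanoRecord | None:
        """Nearest panorama within ``search_radius`` meters, or None."""

    @abstractmethod
    def fetch_image(self, query: PanoQuery) -> np.ndarray:
        """Return the requested picture as an (H, W, 3) uint8 array."""


class MockProvider(StreetViewProvider):
    """Deterministic provider backed by synthetic scenes.

    Panoramas are declared as ``(pano_id, (x, y))`` pairs.  The scene for a
    (pano_id, heading) pair is derived from a stable CRC of the identifiers,
    so repeated fetches are byte-identical and different headings differ.
    Each pano carries a base green fraction; headings perturb it slightly,
    emulating a camera swinging past the same vegetation.
    """

    def __init__(
        self,
        panos: Sequence[tuple[str, tuple[float, float]]],
        seed: int = 0,
        quota: int = DEFAULT_QUOTA,
        queries_used: int = 0,
    ):
        super().__init__(quota=quota, queries_used=queries_used)
        self.panos = [PanoRecord(pid, tuple(xy)) for pid, xy in panos]
        self.seed = seed

    def find_pano(self, coordinate, search_radius: float = 50.0) -> PanoRecord | None:
        if search_radius <= 0:
            raise ValueError("search_radius must be positive")
        best, best_d = None, float("inf")
        cx, cy = coordinate
        for rec in self.panos:
            d = float(np.hypot(rec.coordinate[0] - cx, rec.coordinate[1] - cy))
            if d <= search_radius and d < best_d:
                best, best_d = rec, d
        return best

    def _scene_seed(self, pano_id: str, heading: float) -> int:
        h = zlib.crc32(f"{pano_id}:{heading:.1f}".encode())
        return (h ^ (self.seed & 0x7FFFFFFF)) & 0x7FFFFFFF

    def ground_truth_fraction(self, pano_id: str, heading: float) -> float:
        """The green fraction the scene for (pano, heading) is built with."""
        base_rng = np.random.default_rng(
            (zlib.crc32(pano_id.encode()) ^ (self.seed & 0x7FFFFFFF)) & 0x7FFFFFFF
        )
        base = base_rng.uniform(0.05, 0.6)
        jitter_rng = np.random.default_rng(self._scene_seed(pano_id, heading))
        return float(np.clip(base + jitter_rng.uniform(-0.05, 0.05), 0.0, 0.9))

    def fetch_image(self, query: PanoQuery) -> np.ndarray:
        from .synthetic import SceneSpec, make_scene  # deferred: avoid cycle

        self._charge()
        pano_id = query.pano_id
        if pano_id is None:
            rec = self.find_pano(query.location)  # type: ignore[arg-type]
            if rec is None:
                raise ProviderError(f"no panorama at {query.location}")
            pano_id = rec.pano_id
        spec = SceneSpec(
            width=query.width,
            height=query.height,
            green_fraction=self.ground_truth_fraction(pano_id, query.heading),
            seed=self._scene_seed(pano_id, query.heading),
        )
        image, _ = make_scene(spec)
        return image


class LocalDirectoryProvider(StreetViewProvider):
    """Reads panoramas from ``root/<pano_id>/<heading>.png``.

    ``root/index.csv`` (columns pano_id, x, y) supplies coordinates for
    place-ID lookups.  Headings are rounded to whole degrees mod 360.
    """

    def __init__(self, root: str | Path, quota: int = DEFAULT_QUOTA, queries_used: int = 0):
        super().__init__(quota=quota, queries_used=queries_used)
        self.root = Path(root)
        index = pd.read_csv(self.root / "index.csv")
        self.records = [
            PanoRecord(str(r.pano_id), (float(r.x), float(r.y)))
            for r in index.itertuples()
        ]

    def find_pano(self, coordinate, search_radius: float = 50.0) -> PanoRecord | None:
        if search_radius <= 0:
            raise ValueError("search_radius must be positive")
        cx, cy = coordinate
        best, best_d = None, float("inf")
        for rec in self.records:
            d = float(np.hypot(rec.coordinate[0] - cx, rec.coordinate[1] - cy))
            if d <= search_radius and d < best_d:
                best, best_d = rec, d
        return best

    def fetch_image(self, query: PanoQuery) -> np.ndarray:
        self._charge()
        if query.pano_id is None:
            rec = self.find_pano(query.location)  # type: ignore[arg-type]
            if rec is None:
                raise ProviderError(f"no panorama at {query.location}")
            pano_id = rec.pano_id
        else:
            pano_id = query.pano_id
        path = self.root / pano_id / f"{int(round(query.heading)) % 360}.png"
        if not path.exists():
            raise ProviderError(f"no image for pano {pano_id} heading {query.heading}")
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
        if arr.shape[:2] != (query.height, query.width):
            arr = np.asarray(
                Image.fromarray(arr).resize((query.width, query.height), Image.BILINEAR)
            )
        return arr


class TencentProvider(StreetViewProvider):
    """Live HTTP dialect (parameters: size, location, pano, heading, pitch, key).

    Network access is never used in the test suite; this class exists so a
    real crawl can reuse the pipeline unchanged.
    """

    IMAGE_URL = "https://apis.map.qq.com/ws/streetview/v1/image"
    PANO_URL = "https://apis.map.qq.com/ws/streetview/v1/getpano"

    def __init__(self, key: str, quota: int = DEFAULT_QUOTA, queries_used: int = 0):
        super().__init__(quota=quota, queries_used=queries_used)
        if not key:
            raise AuthError("a developer key is required for the live service")
        self.key = key

    def image_url(self, query: PanoQuery) -> str:
        params = {
            "size": f"{query.width}x{query.height}",
            "heading": f"{query.heading:g}",
            "pitch": f"{query.pitch:g}",
            "key": self.key,
        }
        if query.pano_id is not None:
            params["pano"] = query.pano_id
        else:
            lat, lon = query.location  # type: ignore[misc]
            params["location"] = f"{lat:.6f},{lon:.6f}"
        return f"{self.IMAGE_URL}?{urllib.parse.urlencode(params)}"

    def find_pano(self, coordinate, search_radius: float = 50.0) -> PanoRecord | None:
        url = (
            f"{self.PANO_URL}?location={coordinate[0]:.6f},{coordinate[1]:.6f}"
            f"&radius={search_radius:g}&key={self.key}"
        )
        try:
            with urllib.request.urlopen(url, timeout=30) as resp:  # pragma: no cover
                import json

                payload = json.load(resp)
        except urllib.error.URLError as exc:  # pragma: no cover
            raise ProviderUnreachableError(str(exc)) from exc
        detail = payload.get("detail") or {}  # pragma: no cover
        if not detail.get("id"):  # pragma: no cover
            return None
        return PanoRecord(  # pragma: no cover
            str(detail["id"]), (float(detail.get("x", 0)), float(detail.get("y", 0)))
        )

    def fetch_image(self, query: PanoQuery) -> np.ndarray:
        self._charge()
        try:
            with urllib.request.urlopen(self.image_url(query), timeout=60) as resp:  # pragma: no cover
                data = resp.read()
        except urllib.error.HTTPError as exc:  # pragma: no cover
            if exc.code in (401, 403):
                raise AuthError(f"key rejected: {exc}") from exc
            raise ProviderUnreachableError(str(exc)) from exc
        except urllib.error.URLError as exc:  # pragma: no cover
            raise ProviderUnreachableError(str(exc)) from exc
        with Image.open(io.BytesIO(data)) as im:  # pragma: no cover
            return np.asarray(im.convert("RGB"))


def build_inventory(
    sites: Sequence[SampleSite],
    provider: StreetViewProvider,
    search_radius: float = 50.0,
    image_dir: str | Path | None = None,
    width: int = MAX_WIDTH,
    height: int = MAX_HEIGHT,
) -> pd.DataFrame:
    """Attempt the four directional pictures for every site.

    Returns one row per (site, heading): columns site_id, segment_id, x, y,
    heading_label, heading_deg, pano_id, file_name, status (ok/missing).
    Sites without a nearby panorama get four ``missing`` rows; per-row
    provider failures are recorded, never aborting the batch.  Images are
    written under ``image_dir/<pano_id>/<heading>.png`` when a directory is
    given.
    """
    rows = []
    image_dir = Path(image_dir) if image_dir is not None else None
    for site in sites:
        rec = provider.find_pano((site.x, site.y), search_radius)
        for label, heading in zip(HEADING_LABELS, site.headings):
            row = {
                "site_id": site.id,
                "segment_id": site.segment_id,
                "x": site.x,
                "y": site.y,
                "heading_label": label,
                "heading_deg": round(heading, 3),
                "pano_id": "" if rec is None else rec.pano_id,
                "file_name": "",
                "status": "missing",
            }
            if rec is not None:
                try:
                    img = provider.fetch_image(
                        PanoQuery(
                            width=width,
                            height=height,
                            pano_id=rec.pano_id,
                            heading=heading % 360.0,
                        )
                    )
                except ProviderError:
                    rows.append(row)
                    continue
                fname = f"{rec.pano_id}/{int(round(heading)) % 360}.png"
                if image_dir is not None:
                    out = image_dir / fname
                    out.parent.mkdir(parents=True, exist_ok=True)
                    Image.fromarray(img, mode="RGB").save(out)
                row["file_name"] = fname
                row["status"] = "ok"
            rows.append(row)
    columns = [
        "site_id",
        "segment_id",
        "x",
        "y",
        "heading_label",
        "heading_deg",
        "pano_id",
        "file_name",
        "status",
    ]
    return pd.DataFrame(rows, columns=columns)
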