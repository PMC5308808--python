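"""Hue-based Green View Index (GVI) computation.

The GVI of a street-level photograph is the fraction of its pixels whose
HSV hue falls inside a green hue range (default 60-180 degrees).  The hue
channel is discretised into 360 one-degree bins; the GVI of an image is the
sum of the bin fractions inside the range, the GVI of a street site is the
arithmetic mean over its (up to four) directional images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from skimage import color

__all__ = [
    "GreenRange",
    "HueHistogram",
    "GVI_CATEGORIES",
    "hue_degrees",
    "hue_bins",
    "hue_histogram",
    "picture_gvi",
    "site_gvi",
    "classify_gvi",
    "calibrate_green_range",
]

#: Category labels and their upper GVI bounds (inclusive); the last is open.
GVI_CATEGORIES = (
    ("not_green", 0.2),
    ("somewhat_green", 0.4),
    ("green", 0.5),
    ("very_green", 1.0),
)


@dataclass(frozen=True)
class GreenRange:
    """Half-open hue interval [lo, hi) in degrees treated as green.

    Integer degree bounds so that the histogram bins partition exactly.
    """

    lo: int = 60
    hi: int = 180

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi <= 360):
            raise ValueError(f"require 0 <= lo < hi <= 360, got [{self.lo}, {self.hi})")


@dataclass
class HueHistogram:
    """360-bin hue distribution of an image.

    ``counts[d]`` is the number of pixels whose hue lies in [d, d+1) degrees.
    Fractions are derived from integer counts so range sums are exact.
    """

    counts: np.ndarray
    counted_pixels: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (360,):
            raise ValueError("hue histogram must have exactly 360 bins")

    @property
    def fractions(self) -> np.ndarray:
        if self.counted_pixels == 0:
            return np.zeros(360)
        return self.counts / self.counted_pixels


def hue_degrees(image: np.ndarray) -> np.ndarray:
    """Per-pixel HSV hue in degrees [0, 360).

    Achromatic pixels (R=G=B) get hue 0 and therefore never count as green.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image has no pixels")
    hsv = color.rgb2hsv(image)
    return hsv[..., 0] * 360.0


def hue_bins(image: np.ndarray) -> np.ndarray:
    """Per-pixel hue bin floor(H) in {0..359}, computed exactly.

    The hexagonal hue of an 8-bit pixel is a rational number (a multiple of
    60 divided by the chroma), so the bin index is obtained with integer
    floor division — no floating-point round-off can move a pixel across a
    bin boundary.  Achromatic pixels land in bin 0.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image has no pixels")
    rgb = image.astype(np.int64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = np.max(rgb, axis=-1)
    d = mx - np.min(rgb, axis=-1)
    safe = np.where(d == 0, 1, d)
    bins = np.select(
        [d == 0, mx == r, mx == g],
        [
            np.zeros_like(d),
            (60 * (g - b)) // safe % 360,
            (60 * (b - r)) // safe + 120,
        ],
        default=(60 * (r - g)) // safe + 240,
    )
    return bins


def hue_histogram(image: np.ndarray) -> HueHistogram:
    """Bin the hue channel of an RGB image into 360 one-degree bins."""
    bins = hue_bins(image)
    counts = np.bincount(bins.ravel(), minlength=360)
    return HueHistogram(counts=counts, counted_pixels=int(bins.size))


def picture_gvi(hist: HueHistogram, green_range: GreenRange = GreenRange()) -> float:
    """Fraction of pixels whose hue lies in ``green_range`` ([lo, hi))."""
    if hist.counted_pixels == 0:
        raise ValueError("histogram counts no pixels")
    return float(hist.counts[green_range.lo : green_range.hi].sum() / hist.counted_pixels)


def site_gvi(per_heading_gvis: Sequence[float], min_images: int = 1) -> float:
    """Site GVI: mean of the per-heading image GVIs (front/back/left/right)."""
    vals = list(per_heading_gvis)
    if len(vals) == 0:
        raise ValueError("site has no images; exclude it upstream")
    if not (min_images <= len(vals) <= 4):
        raise ValueError(f"expected between {min_images} and 4 images, got {len(vals)}")
    return float(np.mean(vals))


def classify_gvi(g: float) -> str:
    """Four-way greenness category.

    not_green (<=0.2), somewhat_green (0.2-0.4], green (0.4-0.5],
    very_green (>0.5).
    """
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"GVI must be in [0, 1], got {g}")
    for label, upper in GVI_CATEGORIES:
        if g <= upper:
            return label
    return GVI_CATEGORIES[-1][0]  # pragma: no cover


def calibrate_green_range(
    images_with_truth: Iterable[tuple[np.ndarray, float]],
    candidate_ranges: Sequence[GreenRange],
) -> tuple[GreenRange, float]:
    """Pick the hue range whose GVI best correlates with ground truth.

    ``images_with_truth`` pairs each image with an independently known green
    fraction (e.g. from manual interpretation or a synthetic mask).  Returns
    the candidate maximising the Pearson correlation, with that correlation.
    """
    pairs = list(images_with_truth)
    if len(pairs) < 10:
        raise ValueError("need at least 10 image/truth pairs to calibrate")
    if len(candidate_ranges) < 2:
        raise ValueError("need at least 2 candidate ranges")
    truth = np.array([t for _, t in pairs], dtype=float)
    if np.ptp(truth) == 0:
        raise ValueError("ground truth is constant; correlation undefined")
    hists = [hue_histogram(img) for img, _ in pairs]
    best: tuple[GreenRange, float] | None = None
    for rng in candidate_ranges:
        gvis = np.array([picture_gvi(h, rng) for h in hists])
        if np.ptp(gvis) == 0:
            r = 0.0  # a range that never responds carries no signal
        else:
            r = float(stats.pearsonr(gvis, truth).statistic)
        if best is None or r > best[1]:
            best = (rng, r)
    assert best is not None
    return best
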