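# Methods

This note documents the models, procedures and numerical choices behind
`greenview`, what the synthetic data does and does not emulate, and the
design decisions taken where the problem was genuinely open.

## 1. The Green View Index

A street-level photograph is converted from RGB to HSV and only the hue
channel is used. Hues are counted into 360 one-degree bins (bin *d* covers
[*d*, *d*+1)); the picture GVI is the fraction of pixels in the green range,
by default [60°, 180°). Half-open range bounds make adjacent ranges
partition cleanly, so GVI over [60, 180) equals the sum of GVI over
[60, 120) and [120, 180).

**Exact binning.** The hexagonal hue of an 8-bit pixel is a rational
number (a multiple of 60 divided by the chroma). `hue_bins` therefore
computes bin indices with integer floor division rather than via a
floating-point hue: no pixel can straddle a bin boundary because of
round-off, and the histogram-sum GVI equals a per-pixel classification
*exactly*, which the test suite asserts against an oracle in exact
rational arithmetic. Achromatic pixels (R=G=B, saturation 0) are assigned
hue 0 and never count as green — gray roads, white walls and black shadows
must not contribute greenery.

**No saturation/value gating by default.** The index is a pure hue
measure; dark-green cars, logos or painted walls are counted as green.
This is a known limitation of color-based vegetation measurement that
segmentation-based approaches address; we deliberately measure the hue
definition faithfully rather than improve on it. `RunConfig` reserves
`min_saturation` / `min_value` knobs for sensitivity analysis.

**Site GVI** is the arithmetic mean of the picture GVIs at a site. When
fewer than four headings return a picture the mean is over what arrived
(≥ 1); sites with zero pictures are excluded and counted in the pipeline
manifest.

**Categories.** GVI values are classified not green (≤ 0.2), somewhat
green (0.2–0.4], green (0.4–0.5], very green (> 0.5); boundary values
belong to the lower class.

**Calibration.** `calibrate_green_range` scores candidate hue ranges by
the Pearson correlation between picture GVI and an independent ground
truth (manual interpretation in a real deployment; the synthetic mask in
tests) and returns the maximizing range with its correlation. Pearson is
used (rank correlation is insensitive to the near-affine distortions that
matter here); constant truth vectors are rejected because the correlation
is undefined.

## 2. Street-network preprocessing and sampling

All geometry runs in a projected planar CRS in meters. Lon/lat input is
reprojected with a spherical azimuthal-equidistant projection centered on
the study area (exact great-circle distances from the center; distortion
over a 3 km disc is negligible for 50 m spacing and 2–30 m buffers). A
heuristic rejects apparently-geographic coordinates (values within lon/lat
bounds *and* sub-degree extent) with an instruction to reproject.

* **Merge divided roads.** Two segments are a dual-carriageway pair when
  they share a road class, their end-to-end directions differ by ≤ 15°
  (mod 180), and their mutual Hausdorff distance is at most the merge
  distance. "Generally parallel" is not defined anywhere authoritative;
  these two thresholds make the contract explicit and testable. The pair
  is replaced by the midline of perpendicular foot-point pairs sampled at
  the longer line's vertices. Pairing is greedy by Hausdorff distance.
* **Unsuitable segments.** Excluded road classes (highways) are dropped by
  attribute; bridges are dropped when a bridge flag exists in the input
  (datasets vary — when the flag is absent only class-based removal
  occurs, and removals are logged).
* **Topology.** Dangles — segments shorter than a threshold (default
  100 m, configurable; the value is not dictated by any source and is a
  logged knob) with a free degree-1 end — are deleted iteratively.
  Pseudo-nodes — degree-2 nodes joining two same-class segments that
  continue roughly straight (direction change ≤ 30°) — are dissolved by
  concatenation, conserving total length to 1e-6 m. The collinearity test
  keeps genuine right-angle corners between two streets intact, which also
  makes the operation idempotent on clean networks. Streets are never
  re-split at crossings.
* **Clipping.** The study area is a disc (default radius 3000 m) around
  the city center; the disc polygon uses 256 segments per quadrant so a
  diameter street clips to its chord length within centimeters.
* **Sampling.** Sites sit at chainages 0, 50, 100, … m; every segment
  contributes at least its start point, so a segment of length *L* yields
  ⌊*L*/50⌋ + 1 sites and short segments are never unrepresented. The
  forward azimuth at a site is that of the polyline edge containing its
  chainage; at an exact vertex the following edge is used, at the terminal
  vertex the trailing edge. Headings are (front, back, left, right) =
  (az, az+180, az+90, az+270) mod 360.

## 3. Providers

`find_pano` returns the nearest panorama within a search radius (default
50 m — the upstream service does not publish its radius, so it is a config
knob), or `None`; absence of a panorama is not an error and is recorded as
`missing` in the inventory, one row per (site, heading) attempt. Transport
failures are a distinct retryable error class and never abort a batch.
Image fetches are charged against a client-side per-key budget of 100,000
queries; place-ID lookups go through a separate endpoint and are not
charged. The counter is monotone within a run and can be seeded from a
persisted value when resuming.

The mock provider derives every scene deterministically from a CRC of
(pano id, heading) xor the provider seed: repeated fetches are
byte-identical, different headings differ, and each pano carries a stable
base green fraction (uniform in [0.05, 0.6]) perturbed by ±0.05 per
heading. The live HTTP dialect is implemented behind the same interface
but never exercised by tests.

## 4. Aggregation

Segment statistics use the population standard deviation (÷n); the choice
between ÷n and ÷(n−1) is not dictated by the method definition, so it is
fixed, documented, and exposed through the groupby machinery if a caller
needs otherwise. `sites_per_km = n_sites / (length/1000)`.

Blocks are the connected components of (study area − street space), where
street space is the union of per-class buffers with half-widths in
[2, 30] m. The default scheme maps road classes linearly onto that range
(widest for the highest road grade); real deployments should override per
class. When no explicit study area is supplied the convex hull of the
network is used, which makes small fixtures behave intuitively (a square
street loop yields exactly its interior block). Block ids are assigned by
sorting polygons on the lower-left corner of their bounding boxes, making
delineation order-independent.

Sites are assigned to the block minimizing Euclidean distance to the block
polygon (zero inside); ties within 1e-9 m go to the smallest block id for
determinism. Block GVI is the mean of assigned sites, so the
site-count-weighted mean over blocks reproduces the global site mean to
1e-9 — an invariant the acceptance suite checks on random configurations.

Density filters are strict inequalities, read literally from their
definitions: segments kept iff > 13 locations/km, blocks kept iff area
> 1 ha *and* > 1 location/ha.

## 5. City statistics and regression models

**Typology.** The reference pair is the unweighted mean of city means and
of city (population) SDs; a city is High-average / High-SD only when it
strictly exceeds the reference, so ties fall to the Low class on both axes
(a deterministic boundary rule; the choice is arbitrary and documented).

**Moran's I.** Implemented from first principles: row-standardized
weights (default 8-nearest-neighbor on centroids; inverse-distance
available), I = (n/S₀)·zᵀWz/zᵀz, E[I] = −1/(n−1), z-score from the
normality-assumption variance, plus an optional one-sided permutation
pseudo p-value. The implementation is cross-checked in tests against a
brute-force double-loop computation and calibrated on constructed
gradients (positive, significant), permuted values (|z| < 2 in ≥ 90 % of
trials) and checkerboards (I below its expectation). The weights
definition is a genuine free choice — nothing in the method pins it — so
it is a config option.

**Location-level models.** Three nested predictor sets: Model 1
{CENTER, LENGTH} (street-level: air distance to the city center, street
length); Model 2 adds the city controls {SIZE, LEVEL, DENSITY, ECONOMY,
ELEVATION, WATER}; Model 3 adds the region indicators {MIDDLE, WEST}.
Response and predictors are z-scored (population SD) before OLS, so
reported coefficients are standardized and invariant under affine
rescaling of any raw predictor. LEVEL enters as a numeric ordinal (1–4),
consistent with reporting a single coefficient for it. Rank-deficient
designs are rejected with the collinear pairs named. p-values are
classical OLS t-tests without clustering; sites within a city share the
city covariates, so a cluster-robust option would be a reasonable
extension, but the default mirrors the unclustered formulation.

**Backward elimination per administrative level.** Starting from the
Model 3 set (LEVEL excluded as constant within a level; zero-variance
covariates dropped and reported), the least significant predictor is
removed one step at a time until every survivor has p ≤ 0.05. The
procedure is deterministic for identical inputs. Its statistical behavior
should be understood before trusting "exact model recovery": with *k*
irrelevant candidates, the chance that none survives is ≈ (1−α)^k (null
p-values are uniform at any sample size), e.g. ≈ 70 % for k = 7 at
α = 0.05 — so with strong true effects the procedure reliably *retains*
them (power ≈ 1 at n ≈ 20,000 for standardized effects ≥ 0.1) but keeps a
spurious extra in roughly a third of replications. This is a property of
stepwise selection at α = 0.05, not of the implementation.

## 6. Synthetic data: what it emulates, what it does not

**Scenes** emulate the visual structure that matters to a hue-range
measure: coherent canopy blobs (a smoothed Gaussian field thresholded at
the quantile giving the exact target pixel count — not salt-and-pepper
noise), chromatic clutter (sky band 195–250°, facade band 15–50°) and an
achromatic road/building component, at the native 960×640 picture size.
Illumination jitter multiplies the HSV value channel only, so lighting
varies while the hue ground truth stays fixed; saturation/value floors
keep 8-bit quantization from moving any pixel's hue across the green
boundary (chroma ≥ 0.23·255 bounds the round-trip hue error to ~1°, and
hues are sampled ≥ 4° inside the band edges). Scenes are *not*
photorealistic: no geometry, no shadows correlated with objects, no
seasonal leaf-off, no green non-vegetation confounders. A high
mask-vs-GVI correlation on these scenes therefore demonstrates that the
measurement chain (rendering → hue → histogram → range sum → averaging) is
faithful, not that hue-range GVI equals true vegetation in real
photographs — on real imagery the benchmark is manual interpretation.

**Street grids** are r×c node lattices (2rc − r − c segments) with three
seedable pathologies: dual carriageways (parallel same-class pairs at a
configurable offset), dangling stubs (default 40 m, below the dangle
threshold) and pseudo-nodes (collinear splits). They exercise every
preprocessing rule with closed-form expected counts, but contain no
curvature, no class mixtures along a street, and no genuinely ambiguous
parallels.

**Panels** draw city covariates per city (administrative level weighted
toward prefecture-level cities, lognormal size/density/economy, gamma
elevation, Bernoulli water, an east/middle/west region with probabilities
0.5/0.25/0.25) and site covariates per site (distance to center uniform
on the 3 km disc, street length lognormal around the ~150 m national
average). All covariates are z-scored within the panel and the GVI
response is the specified standardized linear combination plus Gaussian
noise (default SD 1), so fitted standardized coefficients estimate the
spec'd values directly. The panel has no spatial structure and no
nonlinearity; it validates estimator correctness, not the realism of any
particular coefficient.

All generators are byte-for-byte reproducible from (spec, seed).

## 7. Problem sizes and tolerances

The test and acceptance runs use desk-scale problem sizes chosen to give
stable statistics at interactive runtimes: 120 scenes at 960×640 for the
validation correlation; 1,000 images ≤ 64×64 for the exactness check;
3×3 grids for geometry oracles; panels of 100 cities × 250–500 sites
(n = 25,000–50,000) for regression recovery; 50 seeds for selection-rate
estimates; 8×8 lattices for Moran calibration. Conservation checks use
1e-9 absolute tolerance; closed-form geometry 1e-6 to 1e-9; length
conservation 1e-6 m. Input formats are GeoJSON and CSV (an ESRI shapefile
reader is not bundled; convert with any GIS tool).

## 8. Known limitations

* Hue-only greenness counts green paint and vehicles as vegetation and
  undercounts backlit or deeply shadowed canopy.
* The thinning of complex interchanges is approximated by the
  dangle/pseudo-node rules plus divided-road merging; full cartographic
  generalization is out of scope.
* City-level covariates describe whole cities while GVI is measured in
  the 3 km center, a known source of ecological bias in the regressions.
* Panorama capture dates are unavailable through the provider interface,
  so seasonal screening must happen outside the pipeline.
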