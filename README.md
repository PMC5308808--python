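# greenview

Automatic assessment of **street greenery** from street-view imagery, for
urban-planning and urban-ecology researchers who want a reproducible,
city-scale measure of how green streets *look* from eye level.

The core quantity is the **Green View Index (GVI)**: the fraction of a
street-level photograph's pixels whose HSV hue falls in a green range. For
an image *I* with hue histogram *p(d)* over 360 one-degree bins,

```
GVI(I) = Σ_{d = 60}^{179} p(d)            (default green range [60°, 180°))
```

and the GVI of a street *site* is the arithmetic mean over the (up to four)
directional pictures — front, back, left, right of the local street
direction — taken at that site. Sites are placed every 50 m along a
simplified street network; site GVIs are aggregated to street segments
(mean and population SD), to urban blocks (polygons left after subtracting
class-dependent street buffers of 2–30 m half-width, each site assigned to
its nearest block), and to cities (mean/SD, a 2×2 high/low-average ×
high/low-SD typology, global Moran's *I* for spatial clustering, and
standardized OLS models of location-level GVI).

The package covers the full workflow as composable library modules plus a
resumable CLI pipeline:

| module                 | role |
|------------------------|------|
| `greenview.synthetic`  | scenes with known vegetation masks, street grids with dual carriageways / dangles / pseudo-nodes, regression panels with known coefficients |
| `greenview.network`    | merge divided roads, remove highways/bridges, enforce topology, clip to a 3 km study disc, sample sites + headings |
| `greenview.provider`   | street-view sources: deterministic mock, local directory, live HTTP dialect (size ≤ 960×640, heading, pitch ∈ [−20°, 90°], per-key quota 100,000) |
| `greenview.gvi`        | exact 360-bin hue histograms, picture/site GVI, four-way greenness categories, green-range calibration |
| `greenview.aggregate`  | segment stats, block delineation, nearest-block assignment, density filters (> 13 sites/km; blocks > 1 ha with > 1 site/ha) |
| `greenview.citystats`  | city summaries and typology, Moran's *I*, nested standardized OLS models, backward elimination per administrative level |
| `greenview.pipeline` / CLI | stage orchestration with manifest, digests and resumability |

## Worked example

Run the whole pipeline on a synthetic city — a 3×3 street grid (200 m
spacing) seeded with two dangling stubs and one pseudo-node, imaged by the
deterministic mock provider at 90 % panorama coverage:

```yaml
# run.yaml
seed: 5
synthetic_network:
  grid_rows: 3
  grid_cols: 3
  spacing: 200
  dangle_count: 2
  pseudo_node_count: 1
excluded_classes: []
image_width: 320
image_height: 214
mock_coverage: 0.9
```

```sh
$ greenview run --config run.yaml --run-dir run
preprocess: segments_in=15, segments_out=12
sample: segments=12, sites=60
fetch: images_missing=4, images_ok=236, rows=240, sites=60
gvi: images_scored=236, sites_excluded=1, sites_with_gvi=59
aggregate: blocks=4, blocks_kept=4, segments_kept=12, segments_with_sites=12
citystats: sites=59
```

Reading the counts: preprocessing repairs the seeded pathologies (15 raw
segments → 12: both dangles deleted, the pseudo-node dissolved); sampling
every 50 m puts 5 sites on each 200 m segment; four pictures are attempted
per site (240), of which 4 are missing because some sites have no panorama
within the 50 m search radius; one site loses all four pictures and is
excluded; the 2×2 interior blocks of the grid are recovered and all units
pass the density filters. City-level output:

```sh
$ cat run/city_summary.csv
n_sites,mean_gvi,std_gvi,not_green,somewhat_green,green,very_green
59,0.300949,0.1757,21,17,12,9
```

i.e. a mean site GVI of 0.30 (SD 0.18) with the 59 sites spread over the
four greenness categories (not green ≤ 0.2 < somewhat green ≤ 0.4 < green
≤ 0.5 < very green). All intermediate artifacts (`network.geojson`,
`sites.csv`, `inventory.csv`, `gvi.csv`, `segments.geojson`,
`blocks.geojson`, `manifest.json`) are plain text files in the run
directory; re-running a completed stage is a no-op unless `--force`d.

The same functionality is available as library calls
(`make_street_grid`, `sample_network`, `build_inventory`,
`picture_gvi`, `delineate_blocks`, `fit_location_models`, …); see the
module docstrings and `docs/methods.md`.

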