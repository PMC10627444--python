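# marshres

Multi-metric tidal-marsh resilience assessment. `marshres` computes thirteen
geospatial metrics per marsh unit, converts them into cohort-relative
decile-rank scores grouped in three categories — current condition,
vulnerability, and adaptive capacity — and combines them into category
scores, a total resilience score, and one of eight High/Low management
categories with linked recommended actions. Results aggregate to any
grouping scale (region, state, reserve, custom labels).

## Metrics

| Category | Metrics (sign) |
|---|---|
| Current condition | area-to-edge ratio (+), unvegetated edge ratio (−), % impervious (−), % natural (+), % agricultural (−) |
| Vulnerability | soil erodibility (−), tidal range (+), % marsh below MHHW (−), % marsh below MTL (−) |
| Adaptive capacity | % hardened shoreline (−, weight 1.5), shoreline complexity (+), migration ratio (+, weight 2.0), wetland connectedness (+) |

Scoring conventions: decile breaks are 10th–90th percentiles (linear
interpolation); a value equal to a break falls in the lower bin;
negative-influence metric ranks are multiplied by −1; vulnerability category
scores run −1 (least) to −10 (most vulnerable); High/Low thresholds are
≥ 6 (≤ −6 for vulnerability). A cohort of at least two units is required —
all scores are relative to the analysis cohort.

Inundation scenarios for the migration ratio default to six one-foot steps
above MHHW (0.3048–1.8288 m) with connected-inundation flood filling;
connectedness is evaluated at a 1.2 m scenario. The land-cover buffer is
150 m. All constants live in `FrameworkConfig` and are overridable via YAML.

## Formats

Everything is plain text: rasters as ESRI ASCII grids (`.asc`), vectors as
GeoJSON, tables as CSV keyed by `unit_id`, class table / configuration /
recommendations as YAML. A landscape directory bundles rasters, tidal
surfaces, shorelines, unit polygons and a manifest. A seeded synthetic
landscape generator (`marshres.generate_landscape`) and a synthetic metric
table generator (`marshres.generate_metric_table`) make the whole pipeline
testable without any external data.

## CLI

```sh
# synthetic fixture
marshres simulate --seed 1 --n-units 10 --shape 200 200 --marsh-fraction 0.3 --out land/

# raster/vector path
marshres metrics --landscape land/ --out metrics.csv
marshres score --metrics metrics.csv --out scores.csv
marshres recommend --scores scores.csv --out mgmt.csv
marshres summarize --scores scores.csv --by region --out summary.csv --counts-out counts.csv

# end-to-end (accepts --landscape DIR or a pre-computed --metrics CSV)
marshres run --landscape land/ --out results/
```

`marshres run` writes `metrics.csv`, `scores.csv`, `management.csv`,
per-label summaries, contingency tables, and a `run_manifest.yaml` (config
hash, input hash, versions); reruns are byte-identical.

## Python API

```python
import marshres

land = marshres.generate_landscape(seed=1, n_units=10, grid_shape=(200, 200), marsh_fraction=0.3)
metrics = marshres.compute_metric_table(land)
scores = marshres.score_table(metrics)
```

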