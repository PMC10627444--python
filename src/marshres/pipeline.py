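"""End-to-end orchestration: rasters/vectors -> metric table -> scores ->
management keys -> summaries, with a run manifest for reproducibility."""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .adaptive import (
    ScenarioSet,
    connectedness,
    migration_ratio,
    pct_hardened_shoreline,
    shoreline_complexity,
)
from .condition import (
    area_to_edge_ratio,
    classify_core_edge,
    landcover_fractions,
    unvegetated_edge_ratio,
)
from .config import FrameworkConfig
from .io import write_metric_table
from .landscape import Landscape
from .management import RecommendationTable, classify_table
from .scoring import score_table
from .summarize import category_count_table, group_summary
from .vulnerability import marsh_mask, mean_erodibility, pct_marsh_below, tidal_range

logger = logging.getLogger("marshres")

__all__ = ["compute_metric_table", "run_pipeline"]


def compute_metric_table(
    landscape: Landscape, config: FrameworkConfig | None = None
) -> pd.DataFrame:
    """All thirteen raw metrics for every unit of a landscape.

    Units without marsh get missing raster metrics; units without shoreline
    get missing shoreline metrics.  Losses are logged so filtering stays
    auditable.
    """
    config = config or FrameworkConfig()
    scenarios = ScenarioSet(tuple(config.scenarios_m))
    lc, ct = landscape.landcover, landscape.class_table
    elev, tides, erod = landscape.elevation, landscape.tides, landscape.erodibility

    masks = {u.unit_id: landscape.unit_mask(u) for u in landscape.units}
    conn = connectedness(
        lc, ct, elev, tides, landscape.units, masks,
        slr=config.connectedness_slr_m, connected=config.connected_inundation,
    )

    rows = []
    n_no_marsh = n_no_shore = 0
    for unit in landscape.units:
        umask = masks[unit.unit_id]
        row: dict[str, object] = {"unit_id": unit.unit_id, **unit.groups}
        mmask = marsh_mask(lc, ct, umask)
        if umask.any() and mmask.any():
            labels = classify_core_edge(lc, ct, umask, connectivity=config.connectivity)
            row["area_to_edge_ratio"] = area_to_edge_ratio(labels)
            row["unveg_edge_ratio"] = unvegetated_edge_ratio(labels)
            row["migration_ratio"] = migration_ratio(
                lc, ct, elev, tides, umask, scenarios, connected=config.connected_inundation
            )
        else:
            n_no_marsh += 1
            row["area_to_edge_ratio"] = row["unveg_edge_ratio"] = row["migration_ratio"] = float("nan")
        row.update(landcover_fractions(lc, ct, unit, buffer_m=config.buffer_m))
        row["soil_erodibility"] = mean_erodibility(erod, umask) if umask.any() else float("nan")
        row["tidal_range_m"] = tidal_range(tides, umask) if umask.any() else float("nan")
        row["pct_below_mhhw"] = pct_marsh_below("mhhw", elev, tides, mmask)
        row["pct_below_mtl"] = pct_marsh_below("mtl", elev, tides, mmask)
        segs = landscape.unit_shorelines(unit.unit_id)
        if segs:
            row["pct_hardened"] = pct_hardened_shoreline(segs)
            row["shoreline_complexity"] = shoreline_complexity(segs)
        else:
            n_no_shore += 1
            row["pct_hardened"] = row["shoreline_complexity"] = float("nan")
        row["connectedness"] = conn.score.get(unit.unit_id, float("nan"))
        rows.append(row)

    logger.info(
        "metrics: %d units in, %d without marsh, %d without shoreline",
        len(landscape.units), n_no_marsh, n_no_shore,
    )
    df = pd.DataFrame(rows).set_index("unit_id")
    return df


def run_pipeline(
    metric_table: pd.DataFrame,
    out_dir,
    config: FrameworkConfig | None = None,
    recommendations: RecommendationTable | None = None,
) -> pd.DataFrame:
    """Score a metric table, attach management keys and recommendations,
    write every artifact plus a run manifest, and return the ScoreTable."""
    config = config or FrameworkConfig()
    recommendations = recommendations or RecommendationTable.default()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_metric_table(metric_table, out / "metrics.csv")
    scores = score_table(metric_table, config.directions())
    scores["management_key"] = classify_table(scores)
    write_metric_table(scores, out / "scores.csv")

    mgmt = pd.DataFrame(
        {
            "management_key": scores["management_key"],
            "actions": [
                "; ".join(recommendations.actions[k]) if isinstance(k, str) else ""
                for k in scores["management_key"]
            ],
        },
        index=scores.index,
    )
    write_metric_table(mgmt, out / "management.csv")

    group_cols = [c for c in metric_table.columns if metric_table[c].dtype == object]
    labels = group_cols or [None]
    for label in labels:
        summary = group_summary(scores, label, ddof=config.sd_ddof)
        summary.to_csv(out / f"summary_{label or 'all'}.csv")
        counts = category_count_table(
            scores["management_key"],
            scores[label] if label else None,
        )
        counts.to_csv(out / f"category_counts_{label or 'all'}.csv")

    metric_hash = hashlib.sha256(
        metric_table.to_csv(index=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "marshres_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "metric_table_hash": metric_hash,
        "n_units": int(len(metric_table)),
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return scores
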