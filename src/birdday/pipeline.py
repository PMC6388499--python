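"""End-to-end orchestration: relocation table in, daily metrics out.

Stage order: project to the plane -> split each animal's track at sunrise
into bird days -> drop incomplete days (raw fix counts) -> drop migratory
days -> remove in-flight fixes -> label fixes by circadian period ->
segment -> group segments into patches -> per-day metrics. Every input
fix is accounted for exactly once across the parse-dropped, incomplete,
migratory, flight-removed and retained counts, and the whole run is a
pure function of (input, config).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import (geometry_to_geojson, project_to_plane, read_relocations,
                 write_geojson)
from .patches import Patch, build_patches, count_revisits, daily_union, sci
from .preprocess import filter_complete_days, flag_migration, remove_flight_fixes, step_metrics
from .segmentation import Segment, classify_segment_period, segment_day, segment_metrics
from .solar import BirdDay, label_fixes, split_bird_days

log = logging.getLogger("birdday")


@dataclass
class DayResult:
    day: BirdDay
    segments: list[Segment]
    patches: list[Patch]


@dataclass
class PipelineResult:
    daily_metrics: pd.DataFrame
    segments: pd.DataFrame
    patch_table: pd.DataFrame
    steps: pd.DataFrame  # per-step rows with circadian + position labels
    days: list[DayResult] = field(repr=False, default_factory=list)
    counts: dict = field(default_factory=dict)


def _tod_label(period: str, crep: str) -> str:
    return crep if crep in ("dawn", "dusk") else period


def _day_tables(day: BirdDay, segments: list[Segment], patches: list[Patch],
                config: RunConfig) -> tuple[dict, list[dict], list[dict], list[dict]]:
    met = segment_metrics(segments, short_max=config.short_segment_max_fixes)
    total_ha, overlap = daily_union(patches)
    sci_pair = sci(patches)
    date = day.date.isoformat()
    base = {
        "animal_id": day.animal_id,
        "date": date,
        "season": day.season,
        "species": day.fixes["species"].iloc[0] if "species" in day.fixes else "",
        "sex": day.fixes["sex"].iloc[0] if "sex" in day.fixes else "",
        "n_fixes": day.n_fixes,
        **met,
        "n_patches": len(patches),
        "total_area_ha": total_ha,
        "overlap_pct": overlap,
        "revisits": count_revisits(patches),
        "sci": sci_pair[0] if sci_pair else np.nan,
        "sci_log": sci_pair[1] if sci_pair else np.nan,
    }
    seg_rows, step_rows = [], []
    for s in segments:
        seg_rows.append({
            "animal_id": day.animal_id, "date": date, "segment_id": s.segment_id,
            "anchor_x": s.anchor_x, "anchor_y": s.anchor_y,
            "n_fixes": s.n_fixes, "duration_h": s.duration_h,
            "duration_class": s.duration_class(config.short_segment_max_fixes),
            "period_class": classify_segment_period(s),
            "entry_step_m": s.entry_step_m,
            "is_day_edge": s.segment_id in (1, len(segments)),
        })
    # full consecutive step series for the day: within-segment steps carry
    # their residency position; steps crossing a segment boundary are the
    # entry moves into the next segment
    sm = step_metrics(day.fixes)
    starts = np.cumsum([0] + [s.n_fixes for s in segments])
    seg_of_fix = np.searchsorted(starts, np.arange(day.n_fixes), side="right")
    for i in range(len(sm)):
        is_entry = seg_of_fix[i] != seg_of_fix[i + 1]
        step_rows.append({
            "animal_id": day.animal_id, "date": date, "step_index": i,
            "segment_id": int(seg_of_fix[i + 1]),
            "is_entry": bool(is_entry),
            "position_index": (np.nan if is_entry
                               else int(i - starts[seg_of_fix[i] - 1])),
            "length_m": float(sm["length_m"].iloc[i]),
            "interval_min": float(sm["interval_min"].iloc[i]),
            "period_label": day.fixes["period"].iloc[i],
            "tod_label": _tod_label(day.fixes["period"].iloc[i],
                                    day.fixes["crepuscular"].iloc[i]),
        })
    patch_rows = []
    for p in patches:
        cx, cy = p.center
        patch_rows.append({
            "animal_id": day.animal_id, "date": date, "patch_id": p.patch_id,
            "n_segments": p.n_segments, "n_fixes": p.n_fixes,
            "area_ha": p.area_ha, "center_x": cx, "center_y": cy,
        })
    return base, seg_rows, patch_rows, step_rows


def run_pipeline(source, config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full daily movement analysis over a relocation table
    (path or DataFrame). When ``out_dir`` is given, writes
    daily_metrics.csv, segments.csv, patches.csv, steps.csv, GeoJSON
    geometries and a run_log.json of filter counts."""
    relocs = read_relocations(source, config)
    relocs = project_to_plane(relocs, config)
    counts = {
        "n_input_fixes": len(relocs) + relocs.attrs.get("n_parse_dropped", 0)
        + relocs.attrs.get("n_duplicates", 0),
        "n_parse_dropped": relocs.attrs.get("n_parse_dropped", 0),
        "n_duplicates": relocs.attrs.get("n_duplicates", 0),
        "n_candidate_days": 0,
        "n_incomplete_day_fixes": 0, "n_migration_fixes": 0,
        "n_flight_removed": 0, "n_retained_fixes": 0,
        "n_incomplete_days": 0, "n_migration_days": 0, "n_retained_days": 0,
        "rng_seed": config.rng_seed,
    }

    results: list[DayResult] = []
    metric_rows, seg_rows, patch_rows, step_rows = [], [], [], []
    for animal_id, track in relocs.groupby("animal_id", sort=True):
        days = split_bird_days(track.reset_index(drop=True), tz=config.tz)
        counts["n_candidate_days"] += sum(1 for d in days if not d.is_partial)
        kept, dropped = filter_complete_days(days, config)
        counts["n_incomplete_days"] += len(dropped)
        counts["n_incomplete_day_fixes"] += sum(d.n_fixes for d in dropped)
        for day in kept:
            if flag_migration(day, config):
                counts["n_migration_days"] += 1
                counts["n_migration_fixes"] += day.n_fixes
                continue
            filtered = remove_flight_fixes(day, config)
            counts["n_flight_removed"] += day.n_fixes - filtered.n_fixes
            counts["n_retained_fixes"] += filtered.n_fixes
            counts["n_retained_days"] += 1
            filtered.fixes = label_fixes(filtered)
            segments = segment_day(filtered, config)
            patches = build_patches(segments, config)
            results.append(DayResult(filtered, segments, patches))
            m, sr, pr, st = _day_tables(filtered, segments, patches, config)
            metric_rows.append(m)
            seg_rows.extend(sr)
            patch_rows.extend(pr)
            step_rows.extend(st)

    daily = pd.DataFrame(metric_rows)
    segments_df = pd.DataFrame(seg_rows)
    patches_df = pd.DataFrame(patch_rows)
    steps_df = pd.DataFrame(step_rows)
    if daily.empty:
        log.warning("run_pipeline: zero retained bird days")

    for stage in ("n_parse_dropped", "n_incomplete_day_fixes", "n_migration_fixes",
                  "n_flight_removed", "n_retained_fixes"):
        log.info("run_pipeline: %s = %d", stage, counts[stage])

    result = PipelineResult(daily, segments_df, patches_df, steps_df, results, counts)
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, config: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.daily_metrics.to_csv(out / "daily_metrics.csv", index=False)
    result.segments.to_csv(out / "segments.csv", index=False)
    result.patch_table.to_csv(out / "patches.csv", index=False)
    result.steps.to_csv(out / "steps.csv", index=False)
    (out / "run_log.json").write_text(json.dumps(result.counts, indent=1) + "\n")

    anchor_feats, patch_feats = [], []
    from shapely.geometry import Point
    for dr in result.days:
        date = dr.day.date.isoformat()
        for s in dr.segments:
            anchor_feats.append({
                "type": "Feature",
                "geometry": geometry_to_geojson(Point(s.anchor_x, s.anchor_y), config),
                "properties": {"animal_id": dr.day.animal_id, "date": date,
                               "segment_id": s.segment_id, "n_fixes": s.n_fixes},
            })
        for p in dr.patches:
            patch_feats.append({
                "type": "Feature",
                "geometry": geometry_to_geojson(p.mcp, config),
                "properties": {"animal_id": dr.day.animal_id, "date": date,
                               "patch_id": p.patch_id, "area_ha": round(p.area_ha, 4)},
            })
    write_geojson(anchor_feats, out / "segment_anchors.geojson")
    write_geojson(patch_feats, out / "patch_mcps.geojson")
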