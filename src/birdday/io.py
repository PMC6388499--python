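"""Reading relocation tables and writing derived products.

The on-disk relocation schema is one CSV row per GPS fix with at least
``animal_id``, ``timestamp`` (ISO 8601, parsed to UTC), ``lon`` and ``lat``
(degrees WGS84); optional ``species`` and ``sex`` columns pass through.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .projection import geographic_to_utm, utm_to_geographic

log = logging.getLogger("birdday")

MANDATORY_COLUMNS = ("animal_id", "timestamp", "lon", "lat")
OPTIONAL_COLUMNS = ("species", "sex")


def read_relocations(source: str | Path | pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Load and clean a relocation table.

    Rows with unparseable timestamps or coordinates are dropped and
    counted in the log; duplicate (animal_id, timestamp) rows keep the
    first occurrence. Output is sorted by (animal_id, timestamp) with
    tz-aware UTC timestamps and drop counts stored in ``df.attrs``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"empty relocation file: {path}")
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    if df.empty:
        raise ValueError("empty relocation table")

    n_raw = len(df)
    df["animal_id"] = df["animal_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    bad = df["timestamp"].isna() | df["lon"].isna() | df["lat"].isna() \
        | (df["lon"].abs() > 180) | (df["lat"].abs() > 90)
    n_parse_dropped = int(bad.sum())
    df = df.loc[~bad]

    df = df.sort_values(["animal_id", "timestamp"], kind="mergesort")
    dup = df.duplicated(subset=["animal_id", "timestamp"], keep="first")
    n_duplicates = int(dup.sum())
    df = df.loc[~dup].reset_index(drop=True)

    if n_parse_dropped:
        log.info("read_relocations: dropped %d unparseable row(s) of %d", n_parse_dropped, n_raw)
    if n_duplicates:
        log.info("read_relocations: dropped %d duplicate (id, timestamp) row(s)", n_duplicates)
    df.attrs["n_parse_dropped"] = n_parse_dropped
    df.attrs["n_duplicates"] = n_duplicates
    return df


def project_to_plane(relocations: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Fill planar UTM coordinates (metres) in columns ``x``/``y``."""
    out = relocations.copy()
    x, y = geographic_to_utm(out["lon"].to_numpy(), out["lat"].to_numpy(),
                             zone=config.utm_zone, north=config.utm_north)
    out["x"] = x
    out["y"] = y
    return out


def unproject(x, y, config: RunConfig):
    """Planar UTM back to (lon, lat) degrees."""
    return utm_to_geographic(np.asarray(x), np.asarray(y),
                             zone=config.utm_zone, north=config.utm_north)


def _ring_to_lonlat(coords, config: RunConfig):
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    lon, lat = unproject(xs, ys, config)
    return [[round(float(lo), 7), round(float(la), 7)] for lo, la in zip(lon, lat)]


def geometry_to_geojson(geom, config: RunConfig) -> dict:
    """Shapely geometry in UTM metres -> GeoJSON geometry dict in WGS84."""
    gt = geom.geom_type
    if gt == "Point":
        lon, lat = unproject([geom.x], [geom.y], config)
        return {"type": "Point", "coordinates": [round(float(lon[0]), 7), round(float(lat[0]), 7)]}
    if gt == "Polygon":
        rings = [_ring_to_lonlat(geom.exterior.coords, config)]
        rings += [_ring_to_lonlat(r.coords, config) for r in geom.interiors]
        return {"type": "Polygon", "coordinates": rings}
    if gt == "MultiPolygon":
        return {"type": "MultiPolygon",
                "coordinates": [geometry_to_geojson(g, config)["coordinates"] for g in geom.geoms]}
    raise TypeError(f"unsupported geometry type {gt}")


def write_geojson(features: list[dict], path: str | Path) -> None:
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")
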