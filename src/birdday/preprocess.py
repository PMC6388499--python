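"""Step metrics and fix/day-level filtering.

Three filters precede segmentation:

* flight removal — a fix whose inbound AND outbound speeds both exceed the
  flight cutoff (default 10 km/h) was acquired mid-flight and is removed,
  with the surviving neighbours bridged by a straight step so distances run
  from one used area to the next;
* completeness — only bird days with a (raw) fix count inside the
  configured range (default 46-49 of the nominal 48) are retained;
* migration — days containing a >= 200 km displacement achieved over
  >= 2 h in a generally north/south direction are excluded.

Completeness is judged on raw counts, before flight removal, so days with
many transit fixes are not spuriously discarded. Speeds always use actual
elapsed time between fixes, never the nominal interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .solar import BirdDay


def step_metrics(fixes: pd.DataFrame) -> pd.DataFrame:
    """Per-step length (m), elapsed interval (min) and speed (km/h).

    Returns n-1 rows for n fixes (empty for fewer than 2), in track order.
    """
    if len(fixes) < 2:
        return pd.DataFrame(columns=["length_m", "interval_min", "speed_kmh"])
    dx = np.diff(fixes["x"].to_numpy())
    dy = np.diff(fixes["y"].to_numpy())
    length = np.hypot(dx, dy)
    dt_min = np.diff(fixes["timestamp"].astype("int64").to_numpy()) / 1e9 / 60.0
    if np.any(dt_min <= 0):
        raise ValueError("non-increasing timestamps in fix sequence")
    speed = (length / 1000.0) / (dt_min / 60.0)
    return pd.DataFrame({"length_m": length, "interval_min": dt_min, "speed_kmh": speed})


def remove_flight_fixes(day: BirdDay, config: RunConfig) -> BirdDay:
    """Drop fixes acquired while flying (in AND out speed > cutoff).

    First and last fixes have only one adjacent step and are never
    removed. Removal re-bridges the survivors and repeats until stable,
    which makes the operation idempotent.
    """
    fixes = day.fixes
    while len(fixes) >= 3:
        steps = step_metrics(fixes)
        spd = steps["speed_kmh"].to_numpy()
        flying = (spd[:-1] > config.flight_speed_kmh) & (spd[1:] > config.flight_speed_kmh)
        if not flying.any():
            break
        keep = np.ones(len(fixes), dtype=bool)
        keep[1:-1] = ~flying
        fixes = fixes.loc[keep].reset_index(drop=True)
    out = BirdDay(
        animal_id=day.animal_id,
        anchor_sunrise=day.anchor_sunrise,
        next_sunrise=day.next_sunrise,
        solar_day=day.solar_day,
        fixes=fixes.reset_index(drop=True),
        season=day.season,
        is_partial=day.is_partial,
    )
    out.n_flight_removed = day.n_fixes - out.n_fixes  # type: ignore[attr-defined]
    return out


def filter_complete_days(days: list[BirdDay], config: RunConfig) -> tuple[list[BirdDay], list[BirdDay]]:
    """Split bird days into (retained, dropped) by raw fix count.

    Partial leading/trailing days never qualify as complete.
    """
    lo, hi = config.fixes_per_day_range
    kept, dropped = [], []
    for d in days:
        if not d.is_partial and lo <= d.n_fixes <= hi:
            kept.append(d)
        else:
            dropped.append(d)
    return kept, dropped


def flag_migration(day: BirdDay, config: RunConfig) -> bool:
    """True when the day contains a migratory displacement: >= 200 km
    between two fixes >= 2 h apart, bearing within +/-45 deg of due north
    or due south."""
    fixes = day.fixes
    n = len(fixes)
    if n < 2:
        return False
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    t = fixes["timestamp"].astype("int64").to_numpy() / 1e9
    min_m = config.migration_distance_km * 1000.0
    min_s = config.migration_min_hours * 3600.0
    tol = config.migration_bearing_tol_deg
    for i in range(n - 1):
        dtv = t[i + 1:] - t[i]
        ok = dtv >= min_s
        if not ok.any():
            continue
        dx = x[i + 1:][ok] - x[i]
        dy = y[i + 1:][ok] - y[i]
        disp = np.hypot(dx, dy)
        far = disp >= min_m
        if not far.any():
            continue
        # bearing from north: 0 = due N, 180 = due S
        bearing = np.degrees(np.arctan2(dx[far], dy[far])) % 360.0
        off_n = np.minimum(bearing, 360.0 - bearing)
        off_s = np.abs(bearing - 180.0)
        if np.any((off_n <= tol) | (off_s <= tol)):
            return True
    return False
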