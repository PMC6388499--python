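"""Run configuration for the bird-day movement pipeline."""

from __future__ import annotations

import datetime as dt
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class RunConfig:
    """All tunables of the daily movement analysis.

    Distances are metres, speeds km/h, intervals minutes. The defaults are
    the analysis constants of the duck-telemetry protocol this package
    implements: a 300 m segmentation/patch-join scale, a 10 km/h flight
    speed cutoff, a 10 m GPS-error buffer, 46-49 fixes for a retainable
    bird day at a 30 min nominal interval, and 10,000 Monte Carlo
    replicates.
    """

    segment_threshold_m: float = 300.0
    flight_speed_kmh: float = 10.0
    gps_buffer_m: float = 10.0
    fixes_per_day_range: tuple[int, int] = (46, 49)
    nominal_interval_min: float = 30.0
    patch_join_m: float = 300.0
    short_segment_max_fixes: int = 2
    mc_replicates: int = 10000
    rng_seed: int = 0
    utm_zone: int = 10
    utm_north: bool = True
    # fixed local-standard offset in hours (default Pacific Standard Time)
    utc_offset_hours: float = -8.0
    migration_distance_km: float = 200.0
    migration_min_hours: float = 2.0
    migration_bearing_tol_deg: float = 45.0

    def __post_init__(self) -> None:
        self.fixes_per_day_range = tuple(self.fixes_per_day_range)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        for name in ("segment_threshold_m", "flight_speed_kmh", "gps_buffer_m",
                     "nominal_interval_min", "patch_join_m", "migration_distance_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        lo, hi = self.fixes_per_day_range
        if lo < 2 or hi < lo:
            raise ValueError(f"fixes_per_day_range must satisfy 2 <= lo <= hi, got {self.fixes_per_day_range}")
        if self.short_segment_max_fixes < 1:
            raise ValueError("short_segment_max_fixes must be >= 1")
        if self.mc_replicates < 1:
            raise ValueError("mc_replicates must be >= 1")
        if not 1 <= self.utm_zone <= 60:
            raise ValueError(f"utm_zone must be in 1..60, got {self.utm_zone}")

    @property
    def tz(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(hours=self.utc_offset_hours))

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixes_per_day_range"] = list(self.fixes_per_day_range)
        return d
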