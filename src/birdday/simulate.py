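"""Synthetic GPS-track generator with ground-truth labels.

The generator emulates the daily movement structure of GPS-tracked
dabbling ducks in a wintering landscape: 48 fixes per bird day at 30 min
intervals from sunrise; residency in a handful of patches with small
isotropic log-normal within-patch steps (median ~20 m) that shrink the
longer the bird stays put; occasional inter-patch flights of ~0.5-1.3 km
concentrated around dawn and dusk, sometimes returning to a patch already
used that day; rare 1-2-fix disturbance excursions a few hundred metres
out and straight back; and transit fixes emitted mid-flight when a hop
spans more than one interval, at a speed above the flight-filter cutoff.

Every fix carries ground-truth segment/patch labels so segmentation and
patch recovery can be scored exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import geographic_to_utm, utm_to_geographic
from .solar import SolarDay

# Suisun Marsh, California
DEFAULT_SITE_LON = -121.98
DEFAULT_SITE_LAT = 38.14


@dataclass
class SimulationConfig:
    """Generative parameters for synthetic bird days.

    Scales follow the telemetry the analysis was designed for: within-patch
    steps with a ~20 m median, inter-patch hops with a ~900 m median,
    flights several times likelier in the dawn/dusk windows, and ln-step
    decay rates of -0.005 (day) and -0.008 (night) per half-hour of
    residency.
    """

    n_birds: int = 5
    n_days: int = 10
    fixes_per_day: int = 48
    interval_min: float = 30.0
    patch_count_mean: float = 3.0      # available patch centres per day
    patch_layout: str = "dispersed"    # dispersed | clustered
    within_step_median_m: float = 20.0
    within_step_log_sd: float = 0.7
    flight_distance_median_m: float = 900.0
    flight_distance_log_sd: float = 0.45
    flight_speed_kmh: float = 12.0     # > filter cutoff so transit fixes are removable
    base_flight_prob: float = 0.05     # per-fix hazard of starting a flight
    dawn_dusk_flight_boost: float = 4.0
    disturbance_rate: float = 0.035    # per-fix hazard of a 1-2-fix excursion
    disturbance_distance_range_m: tuple[float, float] = (400.0, 900.0)
    revisit_prob: float = 0.35
    decay_day: float = -0.005
    decay_night: float = -0.008
    segment_containment_m: float = 240.0  # within-patch walk stays this close to its anchor
    arrival_jitter_m: float = 25.0
    site_lon: float = DEFAULT_SITE_LON
    site_lat: float = DEFAULT_SITE_LAT
    start_date: dt.date = dt.date(2016, 1, 15)
    utc_offset_hours: float = -8.0
    utm_zone: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_flight_prob", "disturbance_rate", "revisit_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.within_step_median_m <= 0 or self.flight_distance_median_m <= 300.0:
            raise ValueError("step medians must be positive; flight distance must exceed 300 m")
        if self.patch_layout not in ("dispersed", "clustered"):
            raise ValueError(f"unknown patch_layout {self.patch_layout!r}")

    @property
    def tz(self) -> dt.timezone:
        return dt.timezone(dt.timedelta(hours=self.utc_offset_hours))


def _draw_patch_centers(cfg: SimulationConfig, rng: np.random.Generator,
                        origin: np.ndarray) -> np.ndarray:
    """Patch centres for one bird day.

    dispersed: sequential random-walk placement with log-normal hop
    distances (so inter-patch flights have the configured scale) and a
    minimum separation well beyond the segmentation threshold.
    clustered: two parent areas far apart, children scattered near the
    parents (Thomas-like), exercising both SCI regimes.
    """
    k = max(1, int(rng.poisson(cfg.patch_count_mean)))
    centers = [origin.copy()]
    if cfg.patch_layout == "clustered":
        parents = [origin, origin + _unit(rng) * 3.0 * cfg.flight_distance_median_m]
        while len(centers) < k:
            parent = parents[int(rng.integers(len(parents)))]
            cand = parent + _unit(rng) * rng.uniform(400.0, 900.0)
            if _min_dist(cand, centers) > 2.5 * 300.0:
                centers.append(cand)
            else:
                continue
        return np.array(centers)
    while len(centers) < k:
        hop = np.exp(np.log(cfg.flight_distance_median_m)
                     + cfg.flight_distance_log_sd * rng.standard_normal())
        cand = centers[-1] + _unit(rng) * hop
        if _min_dist(cand, centers) > 2.5 * 300.0:
            centers.append(cand)
    return np.array(centers)


def _unit(rng: np.random.Generator) -> np.ndarray:
    a = rng.uniform(0, 2 * np.pi)
    return np.array([np.cos(a), np.sin(a)])


def _min_dist(p: np.ndarray, pts: list[np.ndarray]) -> float:
    return min(float(np.hypot(*(p - q))) for q in pts)


def simulate_bird_day(cfg: SimulationConfig, rng: np.random.Generator,
                      animal_id: str = "bird_01",
                      date: dt.date | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One synthetic sunrise-anchored bird day.

    Returns (fixes, ground_truth) with one row per fix each. Fix times run
    from sunrise in steps of the nominal interval; positions are UTM Zone
    metres converted back to WGS84 lon/lat for the on-disk schema.
    """
    date = date or cfg.start_date
    sd = SolarDay.for_date(date, cfg.site_lon, cfg.site_lat, cfg.tz)
    # phase the schedule half an interval past sunrise: tag schedules are
    # not locked to sunrise, and the offset keeps every fix robustly
    # inside [sunrise, next sunrise) despite second-level differences in
    # where sunrise is evaluated
    times = [sd.sunrise + dt.timedelta(minutes=cfg.interval_min * (i + 0.5))
             for i in range(cfg.fixes_per_day)]

    x0, y0 = geographic_to_utm(cfg.site_lon, cfg.site_lat, zone=cfg.utm_zone)
    origin = np.array([float(x0), float(y0)]) + rng.uniform(-2000.0, 2000.0, size=2)
    centers = _draw_patch_centers(cfg, rng, origin)
    k = len(centers)

    def in_crep(t: dt.datetime) -> bool:
        d0, d1 = sd.dawn_window
        k0, k1 = sd.dusk_window
        nd0 = d0 + dt.timedelta(days=1)
        nd1 = d1 + dt.timedelta(days=1)
        return d0 <= t <= d1 or k0 <= t <= k1 or nd0 <= t <= nd1

    cur_patch = int(rng.integers(k))
    visited = {cur_patch}
    seg_id = 1
    seg_anchor = centers[cur_patch] + _unit(rng) * rng.uniform(0, cfg.arrival_jitter_m)
    pos = seg_anchor.copy()
    seg_step = 0  # residency steps taken within the current segment
    next_patch_label = k  # fresh ids for disturbance mini-patches

    rows = []  # (t, x, y, seg, patch, is_flight, is_disturb)
    rows.append((times[0], *pos, seg_id, cur_patch, False, False))

    i = 1
    excursion_return: tuple[np.ndarray, int] | None = None
    excursion_left = 0
    while i < cfg.fixes_per_day:
        t_now = times[i - 1]
        if excursion_left > 0:
            # sit at the excursion point for its remaining fixes; the step
            # draw matches a fresh residency step so it is exchangeable
            # with an ordinary first within-segment step
            step = np.exp(np.log(cfg.within_step_median_m)
                          + cfg.within_step_log_sd * rng.standard_normal())
            pos = pos + _unit(rng) * min(step, cfg.segment_containment_m)
            rows.append((times[i], *pos, seg_id, next_patch_label - 1, False, True))
            excursion_left -= 1
            i += 1
            continue
        if excursion_return is not None:
            # fly straight back to the patch that was left
            back_pos, back_patch = excursion_return
            seg_id += 1
            seg_anchor = back_pos + _unit(rng) * rng.uniform(0, cfg.arrival_jitter_m)
            pos = seg_anchor.copy()
            seg_step = 0
            cur_patch = back_patch
            rows.append((times[i], *pos, seg_id, cur_patch, False, False))
            excursion_return = None
            i += 1
            continue

        u = rng.uniform()
        p_fly = cfg.base_flight_prob * (cfg.dawn_dusk_flight_boost if in_crep(t_now) else 1.0)
        if u < cfg.disturbance_rate:
            # 1-2-fix excursion a few hundred metres out, then return
            excursion_return = (centers[cur_patch].copy(), cur_patch)
            seg_id += 1
            # the excursion point must clear the segmentation scale from
            # both the current anchor and the patch centre it returns to
            for _ in range(50):
                cand = pos + _unit(rng) * rng.uniform(*cfg.disturbance_distance_range_m)
                if (np.hypot(*(cand - seg_anchor)) > 320.0
                        and np.hypot(*(cand - centers[cur_patch])) > 320.0):
                    break
            pos = cand
            rows.append((times[i], *pos, seg_id, next_patch_label, False, True))
            next_patch_label += 1
            excursion_left = int(rng.integers(0, 2))  # 1 or 2 fixes total
            i += 1
            continue
        if u < cfg.disturbance_rate + p_fly and k > 1:
            # inter-patch flight, possibly revisiting a previous patch
            others = [j for j in range(k) if j != cur_patch]
            prev = [j for j in others if j in visited]
            new = [j for j in others if j not in visited]
            if prev and (not new or rng.uniform() < cfg.revisit_prob):
                target = int(rng.choice(prev))
            else:
                target = int(rng.choice(new if new else others))
            dest = centers[target] + _unit(rng) * rng.uniform(0, cfg.arrival_jitter_m)
            hop = float(np.hypot(*(dest - pos)))
            per_interval_m = cfg.flight_speed_kmh * 1000.0 * (cfg.interval_min / 60.0)
            n_transit = int(hop // per_interval_m)
            direction = (dest - pos) / hop
            for s in range(1, n_transit + 1):
                if i >= cfg.fixes_per_day:
                    break
                tp = pos + direction * per_interval_m * s
                rows.append((times[i], *tp, -1, -1, True, False))
                i += 1
            if i >= cfg.fixes_per_day:
                break
            seg_id += 1
            cur_patch = target
            visited.add(target)
            seg_anchor = dest
            pos = dest.copy()
            seg_step = 0
            rows.append((times[i], *pos, seg_id, cur_patch, False, False))
            i += 1
            continue

        # within-patch residency step with circadian ln-step decay
        primary_day = sd.sunrise <= t_now < sd.sunset
        decay = cfg.decay_day if primary_day else cfg.decay_night
        ln_step = (np.log(cfg.within_step_median_m) + decay * seg_step
                   + cfg.within_step_log_sd * rng.standard_normal())
        step = float(np.exp(ln_step))
        cand = pos + _unit(rng) * step
        if np.hypot(*(cand - seg_anchor)) > cfg.segment_containment_m:
            # head back toward the anchor instead of leaving the segment
            back = (seg_anchor - pos)
            back = back / max(np.hypot(*back), 1e-9)
            cand = pos + back * min(step, float(np.hypot(*(seg_anchor - pos))))
        pos = cand
        seg_step += 1
        rows.append((times[i], *pos, seg_id, cur_patch, False, False))
        i += 1

    xs = np.array([r[1] for r in rows])
    ys = np.array([r[2] for r in rows])
    lon, lat = utm_to_geographic(xs, ys, zone=cfg.utm_zone)
    fixes = pd.DataFrame({
        "animal_id": animal_id,
        "timestamp": [r[0].astimezone(dt.timezone.utc) for r in rows],
        "lon": lon,
        "lat": lat,
        "species": "synthetic",
        "sex": "F",
    })
    truth = pd.DataFrame({
        "animal_id": animal_id,
        "timestamp": fixes["timestamp"],
        "true_segment_id": [r[3] for r in rows],
        "true_patch_id": [r[4] for r in rows],
        "is_flight_fix": [r[5] for r in rows],
        "is_disturbance_fix": [r[6] for r in rows],
    })
    return fixes, truth


def true_day_summary(truth: pd.DataFrame) -> dict:
    """Ground-truth per-day counts from per-fix labels."""
    resident = truth[~truth["is_flight_fix"]]
    seg_patch = resident.drop_duplicates("true_segment_id")
    n_segments = seg_patch["true_segment_id"].nunique()
    n_patches = seg_patch["true_patch_id"].nunique()
    revisits = int(n_segments - n_patches)
    return {"true_n_segments": int(n_segments), "true_n_patches": int(n_patches),
            "true_revisits": revisits}


def simulate_population(cfg: SimulationConfig,
                        out_dir: str | Path | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate n_birds x n_days bird days; optionally write fixes.csv and
    ground_truth.csv (schema matching ``io.read_relocations``)."""
    rng = np.random.default_rng(cfg.seed)
    all_fixes, all_truth = [], []
    for b in range(cfg.n_birds):
        animal = f"bird_{b + 1:02d}"
        for d in range(cfg.n_days):
            date = cfg.start_date + dt.timedelta(days=d)
            fixes, truth = simulate_bird_day(cfg, rng, animal_id=animal, date=date)
            all_fixes.append(fixes)
            all_truth.append(truth)
    fixes = pd.concat(all_fixes, ignore_index=True)
    truth = pd.concat(all_truth, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        f = fixes.copy()
        f["timestamp"] = f["timestamp"].map(lambda t: t.isoformat())
        f.to_csv(out / "fixes.csv", index=False)
        tr = truth.copy()
        tr["timestamp"] = tr["timestamp"].map(lambda t: t.isoformat())
        tr.to_csv(out / "ground_truth.csv", index=False)
    return fixes, truth


def simulate_point_pattern(scenario: str, n_short: int, n_long: int, seed: int,
                           field_size: float = 1000.0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Labeled point sets for the three NN-CC calibration scenarios.

    independent: both classes iid uniform on the square.
    associated: short points jittered within field_size/100 of random long points.
    dispersed: long points in a tight central cluster, short points in a
    distant margin band.
    """
    if n_short < 5 or n_long < 5:
        raise ValueError("need at least 5 points per class")
    rng = np.random.default_rng(seed)
    if scenario == "independent":
        short = rng.uniform(0, field_size, size=(n_short, 2))
        long_ = rng.uniform(0, field_size, size=(n_long, 2))
    elif scenario == "associated":
        long_ = rng.uniform(0, field_size, size=(n_long, 2))
        base = long_[rng.integers(0, n_long, size=n_short)]
        ang = rng.uniform(0, 2 * np.pi, size=n_short)
        rad = rng.uniform(0, field_size / 100.0, size=n_short)
        short = base + np.column_stack([np.cos(ang), np.sin(ang)]) * rad[:, None]
    elif scenario == "dispersed":
        center = np.array([field_size / 2.0, field_size / 2.0])
        ang = rng.uniform(0, 2 * np.pi, size=n_long)
        rad = rng.uniform(0, field_size / 20.0, size=n_long)
        long_ = center + np.column_stack([np.cos(ang), np.sin(ang)]) * rad[:, None]
        ang = rng.uniform(0, 2 * np.pi, size=n_short)
        rad = rng.uniform(0.40 * field_size, 0.50 * field_size, size=n_short)
        short = center + np.column_stack([np.cos(ang), np.sin(ang)]) * rad[:, None]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return short, long_
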