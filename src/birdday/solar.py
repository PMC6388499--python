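"""Sunrise/sunset computation and circadian bookkeeping.

Sun times come from the NOAA solar-position equations (the low-precision
ephemeris behind the NOAA solar calculator), refined by one fixed-point
pass so the equation of time and declination are evaluated at the event
itself. Accuracy is a minute or two at mid-latitudes, which is far inside
the half-hour granularity of the GPS fixes being classified.

A "bird day" is the sunrise-to-sunrise 24 h sampling unit: the animal's
track is cut at each local sunrise, and a fix landing exactly on sunrise
opens the new day (half-open [sunrise, next sunrise) convention).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

SEASONS = ("hunt", "post_hunt", "summer", "pre_hunt")

# dawn = [sunrise - 90 min, sunrise + 30 min]; dusk = [sunset - 30 min, sunset + 90 min]
DAWN_BEFORE = dt.timedelta(minutes=90)
DAWN_AFTER = dt.timedelta(minutes=30)
DUSK_BEFORE = dt.timedelta(minutes=30)
DUSK_AFTER = dt.timedelta(minutes=90)

_SUN_ZENITH_DEG = 90.833  # refraction + solar semi-diameter


def _julian_centuries(t_utc: dt.datetime) -> float:
    ts = t_utc.timestamp()
    jd = ts / 86400.0 + 2440587.5
    return (jd - 2451545.0) / 36525.0


def _solar_params(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    l0 = np.deg2rad((280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0)
    m = np.deg2rad(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_ctr = (
        np.sin(m) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * m) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * m) * 0.000289
    )
    true_long = np.rad2deg(l0) + eq_ctr
    omega = np.deg2rad(125.04 - 1934.136 * jc)
    app_long = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = np.deg2rad(mean_obliq + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))
    y = np.tan(obliq / 2.0) ** 2
    eqtime = 4.0 * np.rad2deg(
        y * np.sin(2 * l0)
        - 2.0 * ecc * np.sin(m)
        + 4.0 * ecc * y * np.sin(m) * np.cos(2 * l0)
        - 0.5 * y * y * np.sin(4 * l0)
        - 1.25 * ecc * ecc * np.sin(2 * m)
    )
    return float(eqtime), float(decl)


def _hour_angle_deg(lat_rad: float, decl: float) -> float:
    cos_ha = (
        np.cos(np.deg2rad(_SUN_ZENITH_DEG)) / (np.cos(lat_rad) * np.cos(decl))
        - np.tan(lat_rad) * np.tan(decl)
    )
    if not -1.0 <= cos_ha <= 1.0:
        raise ValueError("sun does not rise/set on this date at this latitude")
    return float(np.rad2deg(np.arccos(cos_ha)))


def sun_times(date: dt.date, lon: float, lat: float,
              tz: dt.tzinfo = dt.timezone.utc) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset instants (tz-aware) for a calendar date at a site.

    ``date`` is interpreted in ``tz`` (the local zone of the study area).
    Latitudes poleward of 66 deg are rejected: the polar day/night regime
    is out of scope for a temperate study area.
    """
    if abs(lat) >= 66.0:
        raise ValueError(f"latitude {lat} unsupported (polar day/night possible)")
    lat_rad = np.deg2rad(lat)
    noon_local = dt.datetime.combine(date, dt.time(12, 0), tzinfo=tz)
    events = []
    for sign in (+1.0, -1.0):  # sunrise, sunset
        t = noon_local.astimezone(dt.timezone.utc)
        for _ in range(3):
            eqtime, decl = _solar_params(_julian_centuries(t))
            ha = _hour_angle_deg(lat_rad, decl)
            minutes_utc = 720.0 - 4.0 * (lon + sign * ha) - eqtime
            base = dt.datetime(t.year, t.month, t.day, tzinfo=dt.timezone.utc)
            cand = base + dt.timedelta(minutes=minutes_utc)
            # keep the event nearest local noon (guards UTC-date rollover)
            for shift in (-1, 0, 1):
                c = cand + dt.timedelta(days=shift)
                if abs((c - noon_local).total_seconds()) < abs((cand - noon_local).total_seconds()):
                    cand = c
            t = cand
        events.append(t.astimezone(tz))
    sunrise, sunset = events
    return sunrise, sunset


@dataclass(frozen=True)
class SolarDay:
    """Sunrise/sunset and the 2 h crepuscular windows for one calendar date."""

    date: dt.date
    sunrise: dt.datetime
    sunset: dt.datetime

    @property
    def dawn_window(self) -> tuple[dt.datetime, dt.datetime]:
        return (self.sunrise - DAWN_BEFORE, self.sunrise + DAWN_AFTER)

    @property
    def dusk_window(self) -> tuple[dt.datetime, dt.datetime]:
        return (self.sunset - DUSK_BEFORE, self.sunset + DUSK_AFTER)

    @classmethod
    def for_date(cls, date: dt.date, lon: float, lat: float, tz: dt.tzinfo) -> "SolarDay":
        sr, ss = sun_times(date, lon, lat, tz)
        return cls(date=date, sunrise=sr, sunset=ss)


def classify_period(timestamp: dt.datetime, solar_day: SolarDay) -> tuple[str, str]:
    """Label an instant as (day|night, dawn|dusk|none).

    Day is the half-open [sunrise, sunset); the crepuscular windows are
    closed at both ends and overlay the primary label (a dawn fix can be
    either night or day depending on which side of sunrise it falls).
    """
    primary = "day" if solar_day.sunrise <= timestamp < solar_day.sunset else "night"
    d0, d1 = solar_day.dawn_window
    k0, k1 = solar_day.dusk_window
    if d0 <= timestamp <= d1:
        crep = "dawn"
    elif k0 <= timestamp <= k1:
        crep = "dusk"
    else:
        crep = "none"
    return primary, crep


def classify_season(date: dt.date) -> str:
    """Season from calendar month: hunt Nov-Jan, post-hunt Feb-Apr,
    summer May-Aug, pre-hunt Sep-Oct."""
    m = date.month
    if m in (11, 12, 1):
        return "hunt"
    if m in (2, 3, 4):
        return "post_hunt"
    if m in (5, 6, 7, 8):
        return "summer"
    return "pre_hunt"


@dataclass
class BirdDay:
    """One animal's sunrise-to-sunrise block of fixes."""

    animal_id: str
    anchor_sunrise: dt.datetime
    next_sunrise: dt.datetime
    solar_day: SolarDay
    fixes: pd.DataFrame = field(repr=False)  # rows of the relocation table
    season: str = ""
    is_partial: bool = False  # leading/trailing block not bounded by sunrises

    def __post_init__(self) -> None:
        if not self.season:
            self.season = classify_season(self.anchor_sunrise.astimezone(
                self.anchor_sunrise.tzinfo).date())

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def date(self) -> dt.date:
        return self.solar_day.date


def split_bird_days(fixes: pd.DataFrame, tz: dt.tzinfo,
                    site: tuple[float, float] | None = None) -> list[BirdDay]:
    """Cut one animal's chronologically ordered fixes at successive sunrises.

    Sunrise for each calendar date is computed at the site coordinates; by
    default the site is that day's first fix. Every fix lands in exactly
    one bird day; the blocks before the first and after the last computed
    sunrise are flagged partial (they are culled later by the completeness
    filter anyway).
    """
    if fixes.empty:
        return []
    if fixes["timestamp"].is_monotonic_increasing is False:
        raise ValueError("fixes must be sorted by timestamp")
    animal_id = str(fixes["animal_id"].iloc[0])

    t0 = fixes["timestamp"].iloc[0].astimezone(tz)
    t1 = fixes["timestamp"].iloc[-1].astimezone(tz)
    dates = pd.date_range(t0.date() - dt.timedelta(days=1),
                          t1.date() + dt.timedelta(days=1), freq="D").date

    local = fixes["timestamp"].dt.tz_convert(tz)
    local_dates = np.array([t.date() for t in local])

    solar_days: dict[dt.date, SolarDay] = {}
    for d in dates:
        mask = local_dates == d
        if site is not None:
            slon, slat = site
        elif mask.any():
            i = int(np.flatnonzero(mask)[0])
            slon, slat = float(fixes["lon"].iloc[i]), float(fixes["lat"].iloc[i])
        else:
            slon, slat = float(fixes["lon"].iloc[0]), float(fixes["lat"].iloc[0])
        solar_days[d] = SolarDay.for_date(d, slon, slat, tz)

    sunrises = sorted(sd.sunrise for sd in solar_days.values())
    ts = fixes["timestamp"]
    days: list[BirdDay] = []
    edges = [None, *sunrises, None]
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo is None:
            mask = ts < hi
            anchor, nxt, partial = ts.iloc[0], hi, True
        elif hi is None:
            mask = ts >= lo
            anchor, nxt, partial = lo, None, True
        else:
            mask = (ts >= lo) & (ts < hi)
            anchor, nxt, partial = lo, hi, False
        block = fixes.loc[mask]
        if block.empty:
            continue
        anchor_local = (anchor if isinstance(anchor, dt.datetime) else anchor.to_pydatetime()).astimezone(tz)
        sd = solar_days.get(anchor_local.date())
        if sd is None:
            sd = SolarDay.for_date(anchor_local.date(), float(block["lon"].iloc[0]),
                                   float(block["lat"].iloc[0]), tz)
        days.append(BirdDay(
            animal_id=animal_id,
            anchor_sunrise=anchor_local,
            next_sunrise=(nxt.astimezone(tz) if nxt is not None else
                          block["timestamp"].iloc[-1].astimezone(tz)),
            solar_day=sd,
            fixes=block.reset_index(drop=True),
            season=classify_season(anchor_local.date()),
            is_partial=partial,
        ))
    return days


def label_fixes(day: BirdDay) -> pd.DataFrame:
    """Return the day's fixes with 'period' (day/night) and 'crepuscular'
    (dawn/dusk/none) columns, classified against the day's solar windows
    and, for fixes past local midnight, the next date's windows."""
    sd = day.solar_day
    tz = day.anchor_sunrise.tzinfo
    next_sd = SolarDay(
        date=sd.date + dt.timedelta(days=1),
        sunrise=day.next_sunrise,
        sunset=sd.sunset + dt.timedelta(days=1),
    )
    periods, creps = [], []
    for t in day.fixes["timestamp"]:
        t = t.to_pydatetime().astimezone(tz)
        primary = "day" if sd.sunrise <= t < sd.sunset else "night"
        d0, d1 = sd.dawn_window
        k0, k1 = sd.dusk_window
        n0, n1 = next_sd.dawn_window
        if d0 <= t <= d1 or n0 <= t <= n1:
            crep = "dawn"
        elif k0 <= t <= k1:
            crep = "dusk"
        else:
            crep = "none"
        periods.append(primary)
        creps.append(crep)
    out = day.fixes.copy()
    out["period"] = periods
    out["crepuscular"] = creps
    return out
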