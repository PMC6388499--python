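import datetime as dt

import numpy as np
import pandas as pd
import pytest

from birdday import RunConfig, SimulationConfig, run_pipeline, simulate_population

UTC = dt.timezone.utc
PST = dt.timezone(dt.timedelta(hours=-8))
SITE_LON, SITE_LAT = -121.98, 38.14


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def small_sim():
    """2 birds x 3 days of synthetic fixes with ground truth."""
    cfg = SimulationConfig(n_birds=2, n_days=3, seed=42)
    fixes, truth = simulate_population(cfg)
    return cfg, fixes, truth


@pytest.fixture(scope="session")
def small_pipeline(small_sim, run_config):
    _, fixes, _ = small_sim
    return run_pipeline(fixes, run_config)


def make_fixes(xy_m, start="2016-01-15T16:00:00+00:00", interval_min=30.0,
               animal_id="b1", site=(SITE_LON, SITE_LAT)):
    """Build a relocation DataFrame from planar offsets (metres) around the
    default study site, with both lon/lat and x/y columns filled."""
    from birdday.projection import geographic_to_utm, utm_to_geographic

    xy = np.asarray(xy_m, dtype=float)
    x0, y0 = geographic_to_utm(site[0], site[1], 10)
    x = x0 + xy[:, 0]
    y = y0 + xy[:, 1]
    lon, lat = utm_to_geographic(x, y, 10)
    t0 = pd.Timestamp(start)
    ts = [t0 + pd.Timedelta(minutes=interval_min * i) for i in range(len(xy))]
    return pd.DataFrame({
        "animal_id": animal_id, "timestamp": ts,
        "lon": lon, "lat": lat, "x": x, "y": y,
    })


def make_bird_day(xy_m, date=dt.date(2016, 1, 15), n_offset_min=15.0,
                  interval_min=30.0, animal_id="b1", with_labels=True):
    """Wrap planar offsets into a BirdDay anchored at the site's sunrise."""
    from birdday.solar import BirdDay, SolarDay, label_fixes

    sd = SolarDay.for_date(date, SITE_LON, SITE_LAT, PST)
    start = sd.sunrise + dt.timedelta(minutes=n_offset_min)
    fixes = make_fixes(xy_m, start=start.isoformat(), interval_min=interval_min,
                       animal_id=animal_id)
    day = BirdDay(animal_id=animal_id, anchor_sunrise=sd.sunrise,
                  next_sunrise=sd.sunrise + dt.timedelta(hours=24),
                  solar_day=sd, fixes=fixes)
    if with_labels:
        day.fixes = label_fixes(day)
    return day
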