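import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birdday import RunConfig
from birdday.segmentation import (estimate_break_point, segment_day,
                                  segment_metrics, classify_segment_period)
from conftest import make_bird_day


def oracle_segment_bounds(xy, threshold):
    """Literal fix-by-fix re-derivation of the anchor rule, kept independent
    of the vectorised implementation."""
    bounds = []
    anchor = None
    for i, p in enumerate(xy):
        if anchor is None or np.hypot(p[0] - anchor[0], p[1] - anchor[1]) > threshold:
            bounds.append(i)
            anchor = p
    return bounds


class TestSegmentDay:
    def test_single_segment_when_all_close(self, run_config):
        rng = np.random.default_rng(0)
        xy = rng.uniform(-100, 100, size=(48, 2))
        segs = segment_day(make_bird_day(xy), run_config)
        assert len(segs) == 1
        assert segs[0].n_fixes == 48

    def test_fix_beyond_300_starts_new_segment(self, run_config):
        segs = segment_day(make_bird_day([[0, 0], [100, 0], [400, 0]]), run_config)
        assert [s.n_fixes for s in segs] == [2, 1]

    def test_exactly_300m_stays(self, run_config):
        segs = segment_day(make_bird_day([[0, 0], [300.0, 0]]), run_config)
        assert len(segs) == 1

    def test_just_over_300m_splits(self, run_config):
        segs = segment_day(make_bird_day([[0, 0], [300.5, 0]]), run_config)
        assert len(segs) == 2

    def test_distance_to_anchor_not_previous_fix(self, run_config):
        # each hop is 200 m but the third fix is 400 m from the anchor
        segs = segment_day(make_bird_day([[0, 0], [200, 0], [400, 0]]), run_config)
        assert [s.n_fixes for s in segs] == [2, 1]

    def test_entry_step_measured_from_previous_segments_last_fix(self, run_config):
        segs = segment_day(make_bird_day([[0, 0], [100, 0], [600, 0]]), run_config)
        assert segs[0].entry_step_m is None
        assert segs[1].entry_step_m == pytest.approx(500.0, rel=1e-6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_fixwise_oracle_and_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        xy = np.cumsum(rng.choice([15.0, 800.0], size=(n, 1)) *
                       rng.standard_normal((n, 2)), axis=0)
        cfg = RunConfig()
        segs = segment_day(make_bird_day(xy), cfg)
        # oracle equivalence on segment boundaries
        got_bounds = []
        acc = 0
        for s in segs:
            got_bounds.append(acc)
            acc += s.n_fixes
        assert got_bounds == oracle_segment_bounds(xy, cfg.segment_threshold_m)
        # partition property
        assert sum(s.n_fixes for s in segs) == n
        # anchor containment
        for s in segs:
            d = np.hypot(s.fixes["x"] - s.anchor_x, s.fixes["y"] - s.anchor_y)
            assert (d <= cfg.segment_threshold_m + 1e-9).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_raising_threshold_never_increases_segments(self, seed):
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.choice([15.0, 500.0], size=(30, 1)) *
                       rng.standard_normal((30, 2)), axis=0)
        day = make_bird_day(xy)
        counts = [len(segment_day(day, RunConfig(segment_threshold_m=t)))
                  for t in (100.0, 300.0, 900.0, 2700.0)]
        assert counts == sorted(counts, reverse=True)


class TestBreakPoint:
    def oracle_break(self, logs, grid_n=4096):
        """Brute-force grid minimiser over an independently evaluated
        Gaussian-sum density with Scott's bandwidth."""
        n = len(logs)
        bw = n ** (-1 / 5) * logs.std(ddof=1)
        grid = np.linspace(logs.min() - 0.5, logs.max() + 0.5, grid_n)
        dens = np.exp(-0.5 * ((grid[:, None] - logs[None, :]) / bw) ** 2).sum(axis=1)
        # two dominant modes by coarse local-max scan
        locmax = [i for i in range(1, grid_n - 1)
                  if dens[i] > dens[i - 1] and dens[i] > dens[i + 1]]
        top2 = sorted(sorted(locmax, key=lambda i: dens[i])[-2:])
        lo, hi = top2
        return float(np.exp(grid[lo + np.argmin(dens[lo:hi + 1])]))

    def test_two_point_masses_break_between(self):
        rng = np.random.default_rng(1)
        lengths = np.concatenate([
            20.0 * np.exp(0.05 * rng.standard_normal(500)),
            2000.0 * np.exp(0.05 * rng.standard_normal(500)),
        ])
        est = estimate_break_point(lengths)
        assert est.ok
        assert 20.0 < est.break_m < 2000.0

    def test_unimodal_reports_failure(self):
        rng = np.random.default_rng(2)
        lengths = 50.0 * np.exp(0.6 * rng.standard_normal(800))
        est = estimate_break_point(lengths)
        assert not est.ok
        assert est.break_m is None

    def test_realistic_mixture_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        lengths = np.concatenate([
            20.0 * np.exp(0.6 * rng.standard_normal(900)),
            1000.0 * np.exp(0.4 * rng.standard_normal(100)),
        ])
        est = estimate_break_point(lengths)
        assert est.ok
        assert 100.0 < est.break_m < 700.0
        oracle = self.oracle_break(np.log(lengths))
        assert est.break_m == pytest.approx(oracle, rel=0.05)

    def test_all_zero_lengths_error(self):
        with pytest.raises(ValueError):
            estimate_break_point(np.zeros(10))

    def test_zero_steps_counted_not_used(self):
        rng = np.random.default_rng(4)
        lengths = np.concatenate([
            np.zeros(10),
            20.0 * np.exp(0.05 * rng.standard_normal(300)),
            2000.0 * np.exp(0.05 * rng.standard_normal(300)),
        ])
        est = estimate_break_point(lengths)
        assert est.n_zero_dropped == 10


class TestSegmentMetrics:
    def test_single_segment_medians(self, run_config):
        segs = segment_day(make_bird_day([[0, 0], [10, 0], [30, 0], [60, 0]]), run_config)
        m = segment_metrics(segs)
        assert m["median_within_step_m"] == pytest.approx(20.0)
        assert m["total_distance_km"] == pytest.approx(0.06)
        assert np.isnan(m["median_entry_step_km"])

    def test_entry_step_median(self, run_config):
        segs = segment_day(make_bird_day([[0, 0], [500, 0]]), run_config)
        m = segment_metrics(segs)
        assert m["median_entry_step_km"] == pytest.approx(0.5)
        assert m["n_segments"] == 2

    def test_48_fix_segment_duration_24h(self, run_config):
        segs = segment_day(make_bird_day(np.zeros((48, 2))), run_config)
        m = segment_metrics(segs)
        assert m["median_duration_h"] == pytest.approx(24.0)

    def test_total_distance_includes_entry_steps(self, run_config):
        segs = segment_day(make_bird_day([[0, 0], [10, 0], [510, 0], [520, 0]]), run_config)
        m = segment_metrics(segs)
        assert m["total_distance_km"] == pytest.approx(0.520)


class TestSegmentPeriod:
    def test_midday_segment_is_day(self, run_config):
        day = make_bird_day(np.zeros((8, 2)), n_offset_min=4 * 60)  # 4 h after sunrise
        segs = segment_day(day, run_config)
        assert classify_segment_period(segs[0]) == "day"

    def test_straddling_sunset_is_crepuscular(self, run_config):
        day = make_bird_day(np.zeros((48, 2)), n_offset_min=15)
        segs = segment_day(day, run_config)
        assert classify_segment_period(segs[0]) == "crepuscular"

    def test_small_hours_segment_is_night(self, run_config):
        day = make_bird_day(np.zeros((4, 2)), n_offset_min=18 * 60)
        segs = segment_day(day, run_config)
        assert classify_segment_period(segs[0]) == "night"
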