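"""Anchor-based path segmentation of a bird day.

A segment is a temporally contiguous run of fixes, each within the
segmentation distance (default 300 m) of the run's first fix (its
"anchor"). Greedy rule: the day's first fix anchors segment 1; each later
fix joins the current segment iff its distance to the current anchor is
<= the threshold, else it anchors a new segment. A fix at exactly the
threshold stays: the bird must MOVE BEYOND that distance to have switched.

The segmentation scale itself can be estimated from the data: the density
of log step lengths is bimodal (small within-area tending steps vs long
inter-area relocations) and its interior minimum marks the spatial break
between the two movement modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .config import RunConfig
from .solar import BirdDay


@dataclass
class Segment:
    segment_id: int
    animal_id: str
    date: object
    anchor_x: float
    anchor_y: float
    fixes: pd.DataFrame = field(repr=False)
    entry_step_m: float | None = None  # previous segment's last fix -> this anchor

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def duration_h(self) -> float:
        return self.n_fixes * 0.5

    def duration_class(self, short_max: int = 2) -> str:
        return "short" if self.n_fixes <= short_max else "long"

    @property
    def within_step_lengths(self) -> np.ndarray:
        dx = np.diff(self.fixes["x"].to_numpy())
        dy = np.diff(self.fixes["y"].to_numpy())
        return np.hypot(dx, dy)


def segment_day(day: BirdDay, config: RunConfig) -> list[Segment]:
    """Assign a (flight-filtered, complete) day's fixes to segments."""
    fixes = day.fixes
    if fixes.empty:
        return []
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    thr = config.segment_threshold_m
    bounds = [0]
    ax, ay = x[0], y[0]
    for i in range(1, len(fixes)):
        if np.hypot(x[i] - ax, y[i] - ay) > thr:
            bounds.append(i)
            ax, ay = x[i], y[i]
    bounds.append(len(fixes))

    segments: list[Segment] = []
    for sid, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        entry = None
        if lo > 0:
            entry = float(np.hypot(x[lo] - x[lo - 1], y[lo] - y[lo - 1]))
        segments.append(Segment(
            segment_id=sid,
            animal_id=day.animal_id,
            date=day.date,
            anchor_x=float(x[lo]),
            anchor_y=float(y[lo]),
            fixes=fixes.iloc[lo:hi].reset_index(drop=True),
            entry_step_m=entry,
        ))
    return segments


@dataclass
class BreakPointEstimate:
    """Interior density minimum of ln(step length) between the two
    dominant movement modes; ``ok`` is False when no bimodal structure is
    found."""

    ok: bool
    break_m: float | None
    mode_locations_m: tuple[float, ...]
    grid_m: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    n_zero_dropped: int = 0


def estimate_break_point(step_lengths_m, n_grid: int = 512) -> BreakPointEstimate:
    """Gaussian KDE of ln(step length); break = argmin of density between
    the two highest modes (back-transformed to metres).

    Zero-length steps are excluded (ln 0 undefined) and counted. Raises
    when no positive lengths remain.
    """
    steps = np.asarray(step_lengths_m, dtype=float)
    pos = steps[steps > 0]
    n_zero = int(len(steps) - len(pos))
    if len(pos) == 0:
        raise ValueError("all step lengths are zero; no break point estimable")
    logs = np.log(pos)
    kde = gaussian_kde(logs)  # Scott's reference bandwidth
    pad = 0.5
    grid = np.linspace(logs.min() - pad, logs.max() + pad, n_grid)
    dens = kde(grid)

    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        return BreakPointEstimate(False, None, tuple(np.exp(grid[maxima])), np.exp(grid), dens, n_zero)
    top2 = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    return BreakPointEstimate(
        ok=True,
        break_m=float(np.exp(grid[valley])),
        mode_locations_m=tuple(float(np.exp(grid[i])) for i in sorted(top2)),
        grid_m=np.exp(grid),
        density=dens,
        n_zero_dropped=n_zero,
    )


def classify_segment_period(segment: Segment) -> str:
    """day iff every member fix is a day fix, night iff every fix is a
    night fix, else crepuscular (requires a 'period' column on the
    segment's fixes)."""
    periods = set(segment.fixes["period"])
    if periods == {"day"}:
        return "day"
    if periods == {"night"}:
        return "night"
    return "crepuscular"


def segment_metrics(segments: list[Segment], short_max: int = 2) -> dict:
    """Per-day summary across a day's segments.

    Total distance sums every step the bird took: within-segment steps
    plus the entry step into each new segment.
    """
    if not segments:
        raise ValueError("no segments")
    within = np.concatenate([s.within_step_lengths for s in segments]) \
        if any(s.n_fixes > 1 for s in segments) else np.array([])
    entries = np.array([s.entry_step_m for s in segments if s.entry_step_m is not None])
    total_m = float(within.sum() + entries.sum())
    n_short = sum(1 for s in segments if s.n_fixes <= short_max)
    return {
        "n_segments": len(segments),
        "n_short_segments": n_short,
        "median_within_step_m": float(np.median(within)) if within.size else np.nan,
        "median_entry_step_km": float(np.median(entries)) / 1000.0 if entries.size else np.nan,
        "median_duration_h": float(np.median([s.duration_h for s in segments])),
        "total_distance_km": total_m / 1000.0,
    }
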