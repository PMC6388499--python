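#!/usr/bin/env python
"""Circadian movement patterns, autocorrelation and within-segment decay.

From the pipeline's per-step table: the probability of a long (> 300 m)
move by dawn/day/dusk/night, day-level vs within-segment lag-1 step
autocorrelation, and the pooled ln-step decay slope against residency
time separately for day and night. Writes results/circadian_summary.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from birdday import ar1_per_day, critical_r, period_move_prob, step_decay_slope

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    steps_path = PIPE / "steps.csv"
    if not steps_path.exists():
        raise SystemExit(f"{steps_path} missing - run analysis/02_daily_movement_metrics.py first")
    steps = pd.read_csv(steps_path)

    move_prob = period_move_prob(steps, threshold_m=300.0, label_col="tod_label")
    print("probability of a > 300 m step by circadian period:")
    print(move_prob.to_string(float_format=lambda v: f"{v:.4f}"))

    steps = steps.sort_values(["animal_id", "date", "step_index"])
    day_series = [g["length_m"].to_numpy()
                  for _, g in steps.groupby(["animal_id", "date"])]
    within = steps[~steps["is_entry"]]
    seg_series = [g["length_m"].to_numpy()
                  for _, g in within.groupby(["animal_id", "date", "segment_id"])]
    day_r, day_skipped = ar1_per_day(day_series)
    seg_r, seg_skipped = ar1_per_day(seg_series)
    n_steps = int(steps.groupby(["animal_id", "date"]).size().median())

    out = {
        "move_prob_by_period": {
            p: {"n_steps": int(r["n_steps"]), "p_long": float(r["p_long"])}
            for p, r in move_prob.iterrows()},
        "ar1_day": day_r,
        "ar1_within_segment": seg_r,
        "critical_r": critical_r(n_steps + 1),
        "decay_slope_day": step_decay_slope(steps, "day"),
        "decay_slope_night": step_decay_slope(steps, "night"),
    }
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "circadian_summary.json").write_text(json.dumps(out, indent=1) + "\n")
    print(f"\nday-level AR(1) = {day_r:.3f}, within-segment AR(1) = {seg_r:.3f} "
          f"(critical r = {out['critical_r']:.2f}; {day_skipped}/{seg_skipped} "
          "degenerate day/segment series skipped)")
    print(f"ln-step decay per fix of residency: day {out['decay_slope_day']:.4f}, "
          f"night {out['decay_slope_night']:.4f}")


if __name__ == "__main__":
    main()
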