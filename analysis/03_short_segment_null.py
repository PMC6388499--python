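#!/usr/bin/env python
"""Short-duration segments: random-break null and spatial dispersion.

Two questions about the 1-2-fix ("short duration") track segments:

1. Do they occur more often than expected if segment breaks fell at
   random among the day's 48 fixes?  Compares the observed short-segment
   fraction with the closed-form random-break expectation under the
   observed segments-per-day distribution, with and without the segments
   touching the day boundary (sunrise-splitting artefacts).
2. Are their anchor points spatially dispersed relative to long-duration
   segments?  One-way nearest-neighbor cross-class Monte Carlo test with
   10,000 label permutations.

Writes results/short_segment_null.json.
"""

import json
from pathlib import Path

import pandas as pd

from birdday import RunConfig, expected_short_fraction, nncc_test, short_excess

ROOT = Path(__file__).resolve().parents[1]
PIPE = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    seg_path = PIPE / "segments.csv"
    if not seg_path.exists():
        raise SystemExit(f"{seg_path} missing - run analysis/02_daily_movement_metrics.py first")
    seg = pd.read_csv(seg_path)
    cfg = RunConfig()

    k_pmf = (seg.groupby(["animal_id", "date"]).size()
             .value_counts(normalize=True).to_dict())
    expected = expected_short_fraction(48, {int(k): float(v) for k, v in k_pmf.items()},
                                       short_max=cfg.short_segment_max_fixes)
    out = {"expected_short_fraction": expected}
    for label, data in (("all_segments", seg),
                        ("interior_segments", seg[~seg["is_day_edge"]])):
        obs = float((data["n_fixes"] <= cfg.short_segment_max_fixes).mean())
        out[label] = {"observed_short_fraction": obs,
                      "excess_pct": short_excess(obs, expected)}

    short = seg.loc[seg["duration_class"] == "short", ["anchor_x", "anchor_y"]].to_numpy()
    long_ = seg.loc[seg["duration_class"] == "long", ["anchor_x", "anchor_y"]].to_numpy()
    res = nncc_test(short, long_, B=cfg.mc_replicates, seed=cfg.rng_seed)
    out["nncc"] = {"observed_mean_m": res.observed_mean_m, "p_value": res.p_value,
                   "B": res.B, "n_short": len(short), "n_long": len(long_)}

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "short_segment_null.json").write_text(json.dumps(out, indent=1) + "\n")
    print(json.dumps(out, indent=1))
    print("\nshort segments occur "
          f"{out['all_segments']['excess_pct']:.0f}% more often than the random-break "
          f"expectation; NN-CC p = {res.p_value:.4f} "
          "(p < 0.05 = short anchors dispersed relative to long)")


if __name__ == "__main__":
    main()
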