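"""Descriptive statistics over bird days and segments: lag-1 step-length
autocorrelation, bootstrap medians, circadian movement probabilities, and
the within-segment step-decay slope."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def ar1(series) -> float:
    """Lag-1 sample autocorrelation (acf-style: overall mean, biased
    denominator). NaN for series shorter than 3 or with zero variance."""
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        return np.nan
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    if denom == 0:
        return np.nan
    return float((xc[:-1] * xc[1:]).sum() / denom)


def ar1_per_day(step_lengths_by_day: list[np.ndarray]) -> tuple[float, int]:
    """Mean lag-1 autocorrelation of the step-length series across days.

    Returns (mean AR(1), number of degenerate days skipped). Days with
    fewer than 3 steps or zero variance are skipped.
    """
    vals = [ar1(s) for s in step_lengths_by_day]
    good = [v for v in vals if not np.isnan(v)]
    if not good:
        raise ValueError("no day with a computable AR(1)")
    return float(np.mean(good)), len(vals) - len(good)


def critical_r(n_pairs: int, alpha: float = 0.05) -> float:
    """Two-tailed critical value of Pearson's r for n_pairs observations:
    r* = t* / sqrt(t*^2 + df) with df = n_pairs - 2."""
    if n_pairs < 4:
        raise ValueError("need n_pairs >= 4")
    df = n_pairs - 2
    t_star = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_star / np.sqrt(t_star ** 2 + df))


def period_move_prob(steps: pd.DataFrame, threshold_m: float = 300.0,
                     label_col: str = "period_label") -> pd.DataFrame:
    """Empirical probability of a > threshold step per circadian period.

    ``steps`` needs 'length_m' and a label column (default
    'period_label') in {dawn, day, dusk, night}; returns one row per
    observed period with the count of steps and the long-move fraction.
    """
    rows = []
    for period, grp in steps.groupby(label_col):
        n = len(grp)
        rows.append({
            "period": period,
            "n_steps": n,
            "n_long": int((grp["length_m"] > threshold_m).sum()),
            "p_long": float((grp["length_m"] > threshold_m).mean()),
        })
    return pd.DataFrame(rows).set_index("period")


def step_decay_slope(step_table: pd.DataFrame, period: str) -> float:
    """Pooled least-squares slope of ln(step length) on the step's
    within-segment position index, restricted to one period label.

    ``step_table`` needs 'length_m', 'position_index' (0-based index of
    the step within its segment) and 'period_label'. Zero-length steps
    are excluded (log undefined). NaN when fewer than 3 usable steps.
    """
    sub = step_table[(step_table["period_label"] == period) & (step_table["length_m"] > 0)]
    sub = sub.dropna(subset=["position_index"])  # boundary-crossing steps carry no position
    if len(sub) < 3 or sub["position_index"].nunique() < 2:
        return np.nan
    slope, _ = np.polyfit(sub["position_index"].to_numpy(dtype=float),
                          np.log(sub["length_m"].to_numpy()), 1)
    return float(slope)


def median_ci(values, B: int = 2000, seed: int = 0,
              level: float = 0.95) -> dict:
    """Median with a percentile-bootstrap confidence interval.

    For fewer than 5 values only the point estimate is returned.
    """
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    if len(x) < 5:
        return {"median": med, "ci_lo": np.nan, "ci_hi": np.nan, "n": len(x)}
    rng = np.random.default_rng(seed)
    boots = np.median(rng.choice(x, size=(B, len(x)), replace=True), axis=1)
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [a, 1.0 - a])
    return {"median": med, "ci_lo": float(lo), "ci_hi": float(hi), "n": len(x)}
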