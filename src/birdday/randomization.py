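"""Null models: the random-break expectation for locations per segment,
and the one-way nearest-neighbor cross-class (NN-CC) Monte Carlo test.

Random-break null
-----------------
If a day of n locations is cut into k segments by choosing k-1 of the
n-1 inter-fix gaps uniformly at random (all compositions of n into k
positive parts equally likely), the length L of a uniformly chosen
segment has the closed form

    P(L = l | n, k) = C(n-l-1, k-2) / C(n-1, k-1),   1 <= l <= n-k+1,

(point mass at n for k = 1). The expected short-segment fraction under an
observed segments-per-day distribution weights P(L <= s | k) by the
expected number of segments each day contributes, i.e. by k.

NN-CC test
----------
The observed statistic is the mean distance from each short-duration
anchor to its nearest long-duration anchor. The null randomly reassigns
the class labels over the pooled anchor positions, keeping class sizes
fixed; the upper-tail Monte Carlo p-value is
(1 + #{replicate >= observed}) / (B + 1). Independence gives p near 0.5,
spatial association (short intermixed with long) p near 1, and spatial
segregation/dispersion p below 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import comb


def expected_segment_length_pmf(n_locations: int, k_segments: int) -> np.ndarray:
    """pmf over segment lengths 1..n (index l-1 holds P(L = l)) under the
    uniform random-break model."""
    n, k = int(n_locations), int(k_segments)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    pmf = np.zeros(n)
    if k == 1:
        pmf[n - 1] = 1.0
        return pmf
    lengths = np.arange(1, n - k + 2)
    pmf[:len(lengths)] = comb(n - lengths - 1, k - 2) / comb(n - 1, k - 1)
    return pmf


def expected_short_fraction(n_locations: int, segments_per_day_pmf: dict[int, float],
                            short_max: int = 2) -> float:
    """Expected fraction of segments with <= short_max locations, mixing
    over the segments-per-day distribution weighted by segment count."""
    ks = np.array(sorted(segments_per_day_pmf))
    pk = np.array([segments_per_day_pmf[int(k)] for k in ks], dtype=float)
    if not np.isclose(pk.sum(), 1.0, atol=1e-9):
        raise ValueError(f"segments-per-day pmf sums to {pk.sum()}, not 1")
    short_given_k = np.array([
        expected_segment_length_pmf(n_locations, int(k))[:short_max].sum() for k in ks
    ])
    return float((pk * ks * short_given_k).sum() / (pk * ks).sum())


def short_excess(observed_short_fraction: float, expected_short_fraction: float) -> float:
    """Relative excess of observed over expected short-segment fraction, %."""
    if expected_short_fraction <= 0:
        raise ValueError("expected short fraction must be positive")
    return 100.0 * (observed_short_fraction - expected_short_fraction) / expected_short_fraction


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Expand one master seed into n decorrelated 31-bit child seeds via
    numpy's SeedSequence, for repetition studies that need one independent
    stream per dataset."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in (ss.generate_state(n, dtype=np.uint32) >> 1)]


@dataclass
class NnccResult:
    observed_mean_m: float
    replicate_means_m: np.ndarray
    p_value: float
    B: int
    seed: int

    def __repr__(self) -> str:  # replicate vector elided
        return (f"NnccResult(observed_mean_m={self.observed_mean_m:.2f}, "
                f"p_value={self.p_value:.4f}, B={self.B}, seed={self.seed})")


def _mean_nn_cross(short_pts: np.ndarray, long_pts: np.ndarray) -> float:
    tree = cKDTree(long_pts)
    d, _ = tree.query(short_pts, k=1)
    return float(np.mean(d))


def nncc_test(short_points, long_points, B: int = 10000, seed: int = 0) -> NnccResult:
    """One-way NN cross-class Monte Carlo test (short -> nearest long)."""
    short_pts = np.atleast_2d(np.asarray(short_points, dtype=float))
    long_pts = np.atleast_2d(np.asarray(long_points, dtype=float))
    if len(short_pts) < 1 or len(long_pts) < 1 or len(short_pts) + len(long_pts) < 2:
        raise ValueError("need at least one point in each class")
    observed = _mean_nn_cross(short_pts, long_pts)

    pooled = np.vstack([short_pts, long_pts])
    n_short, n_tot = len(short_pts), len(pooled)
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    if n_tot <= 1500:
        # full pairwise distances make each relabeling a cheap slice
        diff = pooled[:, None, :] - pooled[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=-1))
        for b in range(B):
            perm = rng.permutation(n_tot)
            s_idx, l_idx = perm[:n_short], perm[n_short:]
            reps[b] = dist[np.ix_(s_idx, l_idx)].min(axis=1).mean()
    else:
        for b in range(B):
            perm = rng.permutation(n_tot)
            reps[b] = _mean_nn_cross(pooled[perm[:n_short]], pooled[perm[n_short:]])
    p = (1.0 + np.sum(reps >= observed)) / (B + 1.0)
    return NnccResult(observed_mean_m=observed, replicate_means_m=reps,
                      p_value=float(p), B=B, seed=seed)
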