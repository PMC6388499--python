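# birdday

Daily spatio-temporal movement analysis for GPS-tracked waterfowl.

High-frequency (30 min) GPS telemetry of dabbling ducks shows that most of a
bird's day is spent sitting in a handful of small wetland patches, punctuated
by sub-kilometre forage–roost flights concentrated around dawn and dusk. This
package turns raw relocation tables into the per-day movement and space-use
metrics that describe that structure, for movement ecologists working with
diurnally-structured telemetry:

- **bird days** — the track is cut at each local sunrise into 24 h units of
  48 nominal fixes, with every fix labelled day/night and dawn/dusk
  (dawn = 1.5 h before to 0.5 h after sunrise; dusk symmetric around sunset);
- **flight filtering** — a fix whose inbound *and* outbound speeds both
  exceed 10 km h⁻¹ was acquired mid-flight and is removed, so distances run
  from one used area to the next; days with a ≥ 200 km, ≥ 2 h,
  roughly north–south displacement are excluded as migratory;
- **segments** — a greedy anchor rule: each fix joins the current segment iff
  it lies within *d* = 300 m of the segment's first fix, else it anchors a
  new segment. Segments of 1–2 fixes (≤ 1 h) are "short duration". The 300 m
  scale can be re-estimated from the data as the interior minimum of the
  kernel density of ln(step length), which is bimodal (within-patch steps,
  median ≈ 20 m, vs inter-patch flights, ≈ 0.5–1.3 km);
- **patches** — segments whose anchors lie within 300 m (single linkage) are
  one patch; each patch carries a minimum convex polygon over its 10 m
  GPS-error-buffered fixes, and per day the package reports patch count,
  union area, MCP overlap, and revisits (segments beyond the first per patch);
- **SCI**, the spatiotemporal contagion index — with patch centres *cᵢ*,
  time weights *wᵢ* (fix count) and the layout centre *c̄*,

  SCI = SD_w / SD_u, SD_w = √(Σᵢ wᵢ‖cᵢ − c̄‖² / Σᵢ wᵢ), SD_u = √(Σᵢ ‖cᵢ − c̄‖² / n)

  so SCI < 1 when time concentrates in mutually clustered patches, > 1 when
  it concentrates in a patch remote from the rest, and exactly 1 when time
  is spread equally;
- **null models** — (i) a closed-form random-break null for the number of
  locations per segment, P(L = ℓ | n, k) = C(n−ℓ−1, k−2)/C(n−1, k−1),
  giving the short-segment fraction expected if segment breaks fell at
  random among the day's fixes; (ii) a one-way nearest-neighbour cross-class
  (NN-CC) Monte Carlo test comparing the observed mean short→long anchor
  distance against 10,000 label permutations, with
  p = (1 + #{replicate ≥ observed})/(B + 1): ≈ 0.5 under independence,
  ≈ 0.95 when intermixed, < 0.05 when the short anchors are dispersed;
- **descriptives** — lag-1 step-length autocorrelation per day and per
  segment with the two-tailed critical r, bootstrap median CIs, probability
  of > 300 m moves by circadian period, and the pooled ln-step decay slope
  against within-segment residency time.

Because no telemetry is bundled, a first-class synthetic generator
(`birdday.simulate`) produces GPS tracks with the same statistical structure
— patch residency with decaying log-normal steps, crepuscular-boosted
flights, revisits, 1–2-fix disturbance excursions — plus full ground-truth
labels, so segmentation and patch recovery can be scored exactly.

## Worked example

```python
from birdday import RunConfig, SimulationConfig, run_pipeline, simulate_population

fixes, truth = simulate_population(SimulationConfig(n_birds=2, n_days=3, seed=42))
res = run_pipeline(fixes, RunConfig())
print(res.daily_metrics[["animal_id", "date", "n_segments", "n_patches",
                         "revisits", "total_distance_km", "total_area_ha", "sci"]])
```

```
  animal_id        date  n_segments  n_patches  revisits  total_distance_km  total_area_ha       sci
0   bird_01  2016-01-15          12          7         5          10.094016       2.693245  0.657927
1   bird_01  2016-01-16           5          4         1           5.793492       2.961835  1.053670
2   bird_01  2016-01-17           6          4         2           5.312429       3.637641  1.134555
3   bird_02  2016-01-15          13          8         5          15.857285       2.025689  0.965399
4   bird_02  2016-01-16          13          7         6          18.978656       3.749672  1.128704
5   bird_02  2016-01-17           7          4         3           5.833330       1.994535  0.842086
```

On the first day, twelve segments grouped into seven patches: the bird
returned five times to areas it had already used, covering 10.1 km and
2.7 ha in total, with an SCI of 0.66 — its time was concentrated among the
mutually clustered patches rather than the remote ones.

The numbered drivers under `analysis/` run the full study on a 500-bird-day
simulation (`python analysis/01_simulate_tracks.py` … `04_…`), writing
summary tables to `results/`. On the default configuration they report, e.g.,
a median total daily distance of 6.7 km, median within-segment step of
19.0 m, median entry step of 0.82 km, short segments occurring 59% more
often than the random-break expectation with NN-CC p = 0.0034 (short-segment
anchors dispersed relative to long), and > 300 m move probabilities of
0.199/0.213 at dawn/dusk versus 0.103/0.106 in day/night.

CLI equivalents: `birdday simulate`, `birdday run`, `birdday nncc`.

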