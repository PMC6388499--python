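# Methods

## The sampling unit

The analysis treats a 24 h sunrise-to-sunrise block — a *bird day* — as the
unit of observation, because waterfowl movement is organised by the
photoperiod: the long forage–roost flights happen around dawn and dusk, so
cutting at sunrise keeps each day's used areas intact. Sunrise and sunset
come from the NOAA solar-position equations (equation of time + declination,
zenith 90.833° for refraction and solar semi-diameter), refined by a
fixed-point pass so both are evaluated at the event itself; accuracy is a
minute or two at mid-latitudes, far below the 30 min fix granularity. Solar
times are evaluated at each day's first fix; bird-day membership is the
half-open interval [sunrise, next sunrise), so a fix exactly at sunrise
opens the new day. Crepuscular windows (dawn: sunrise − 90 min to
+ 30 min; dusk: sunset − 30 min to + 90 min) are closed at both ends and
overlay the day/night label. Local time uses a fixed standard offset
(default UTC−8) rather than civil DST, so window boundaries never jump by
an hour mid-study. Seasons are calendar months: hunt Nov–Jan, post-hunt
Feb–Apr, summer May–Aug, pre-hunt Sep–Oct, assigned from the anchor
sunrise's month.

Coordinates are WGS84 lon/lat on disk and UTM metres (default Zone 10 N) in
memory. The transverse-Mercator mapping is the 6th-order Krüger/Karney
series — sub-millimetre inside a zone, with the inverse closed by Newton
iteration on the conformal latitude — so planar Euclidean step lengths are
faithful to geodesic distances at landscape scale.

## Filters

*Flight fixes.* A fix is in-flight iff its inbound and outbound speeds both
exceed 10 km h⁻¹ (strictly; ties retained), a cutoff above duck
walking/swimming speed and below flight speed. Speeds always use actual
elapsed time. Removal re-bridges surviving neighbours and repeats to a
fixed point, which makes the operation idempotent — a single pass is not,
because a bridged step can itself exceed the cutoff. First/last fixes have
one adjacent step only and are never removed.

*Completeness.* Days with a raw fix count in [46, 49] (of the nominal 48 at
30 min) are retained. The count is taken before flight removal so that
days with many transit fixes are not spuriously discarded; the bound is
configurable.

*Migration.* A day is excluded when any fix pair ≥ 2 h apart shows a
≥ 200 km displacement bearing within ±45° of due north or south. The ±45°
quantifies "generally northerly or southerly"; no tolerance is canonical,
and at 200 km scale the flag is insensitive to the exact cone.

Every input fix lands in exactly one of {parse-dropped, duplicate,
incomplete-day, migratory-day, flight-removed, retained}; the pipeline log
records all six counts, and the whole run is a pure function of
(input, config).

## Segmentation and patches

Segmentation is the greedy anchor rule at *d* = 300 m. The boundary case
(exactly 300 m) stays in the segment: the bird must move *beyond* the
threshold to have switched. 300 m is both the mean management-unit radius
in the study landscape (~296 m) and the interior break of the log
step-length density; the package ships the constant as configuration *and*
an estimator (`estimate_break_point`: Gaussian KDE of ln(step length),
Scott's bandwidth, 512-point grid, break = density minimum between the two
highest modes, failure flag when unimodal, zero-length steps excluded and
counted) without asserting which came first. Short-duration segments are
those of ≤ 2 fixes (≤ 1 h).

Patches group segments whose anchors lie within 300 m under *single
linkage* — chaining allowed — because patch membership in the field sense
("returned to an area previously used") is transitive. Patch area is the
convex hull of the union of 10 m GPS-error disks around member fixes
(32 quadrant segments per disk, ~0.2% polygonal area error), so even a
1-fix patch has positive area (π·10² m² ≈ 0.031 ha). Daily total area is
the geometric union of patch MCPs; overlap% = 100·(Σ areas − union)/Σ areas.
Revisits per day = Σ over patches of (member segments − 1).

## The spatiotemporal contagion index

SCI asks *where the day's time went*: among mutually clustered patches, or
in a patch remote from the rest. With patch centres cᵢ (mean of member
fixes), weights wᵢ = fix count (1 fix = 30 min), and the unweighted layout
centre c̄:

    SD_u = sqrt( Σᵢ ||cᵢ − c̄||² / n )
    SD_w = sqrt( Σᵢ wᵢ ||cᵢ − c̄||² / Σᵢ wᵢ )
    SCI  = SD_w / SD_u

Both standard distances are taken about the *same* (unweighted) centre.
This is a deliberate design choice: re-centring the weighted variance on
the weighted mean would make SCI < 1 whenever time concentrates *anywhere*
(concentration always shrinks variance about its own centroid), destroying
the index's directional meaning. Keeping the geometric reference fixed
makes the three anchors hold simultaneously and exactly: equal weights →
SCI = 1 for any layout; weight concentrated in a patch remote from the
layout centre → SCI > 1; weight concentrated in a clustered group → SCI < 1.
SCI is invariant to rescaling coordinates or weights, is defined only for
≥ 3 patches with non-coincident centres, and is reported alongside
ln(SCI), the scale on which daily values are summarised (clustered use
gives small negative medians).

## Null models

*Random-break null for segment durations.* If a day of n locations is cut
into k segments by choosing k − 1 of the n − 1 inter-fix gaps uniformly
(all compositions of n into k positive parts equally likely), the length of
a uniformly chosen segment has pmf P(L = ℓ) = C(n−ℓ−1, k−2)/C(n−1, k−1).
The expected short-segment fraction under an observed segments-per-day
distribution weights P(L ≤ 2 | k) by k (each day contributes k segments).
The closed form is verified against exhaustive enumeration for all n ≤ 12.
The alternative model — multinomial assignment of fixes to segments — was
rejected because segments must be non-empty and temporally contiguous.
The excess statistic is 100·(observed − expected)/expected; the analysis
reports it with and without the segments touching the day boundary, which
are artefacts of cutting tracks at sunrise.

*NN-CC test.* Observed statistic: mean distance from each short-duration
anchor to its nearest long-duration anchor. Null: B random relabelings of
the pooled anchors with class sizes fixed; p = (1 + #{replicate ≥
observed})/(B + 1), upper tail with the +1 correction so p ∈ (0, 1) and the
three interpretation anchors hold (independence ≈ 0.5; association ≈ 0.95;
dispersion < 0.05). For ≤ 1500 points the pooled distance matrix is
precomputed and each replicate is a slice; above that, a KD-tree per
replicate. Same seed ⇒ identical replicate vector. Regional stratification
is a pass-through grouping column, not hard-coded geography.

## Descriptive statistics

Lag-1 autocorrelation of the step-length series is the acf-style estimator
(overall mean, biased denominator), averaged across days (all consecutive
steps including entry steps) and across segments (within-segment steps
only); zero-variance series are skipped and counted. Note the within-
segment average inherits the small-sample bias of the sample ACF
(≈ −1/(n−1) for short series) exactly as the field-standard estimator
does. The critical value is r* = t*/√(t*² + df), df = n_pairs − 2 (48
pairs → 0.28 at α = 0.05). Movement-timing probabilities are empirical
fractions of > 300 m steps per dawn/day/dusk/night label. The
within-segment decay slope is pooled least squares of ln(step length) on
the step's residency index, separately by day/night; this is a
descriptive slope, not a mixed model. Summary medians carry
percentile-bootstrap 95% CIs (B = 2000, seeded); group-level inferential
modelling (LMER/quasi-Poisson with Tukey contrasts) is intentionally out
of scope, so these CIs are descriptive, not model-based.

## Synthetic generator

`simulate_bird_day` emulates the movement structure the analysis assumes:
48 fixes at 30 min from sunrise (phased half an interval past sunrise —
tag schedules are not sunrise-locked, and the offset keeps day membership
robust to second-level differences in where sunrise is evaluated); patch
centres placed by a random walk with log-normal hops (median 900 m, log-sd
0.45, minimum separation 750 m) or, in the "clustered" layout, a
Thomas-like parent–offspring construction that exercises both SCI regimes;
within-patch residency as isotropic log-normal steps (median 20 m, log-sd
0.7) whose ln-mean declines with residency time (−0.005 day, −0.008 night
per fix), reflected at 240 m from the segment anchor so true segments
respect the 300 m scale; flights with per-fix hazard 0.05, boosted ×4 in
the crepuscular windows, revisiting a previous patch with probability
0.35; 1–2-fix disturbance excursions (hazard 0.035/fix) to points 400–900 m
out and > 320 m from both the current anchor and the return patch, then
straight back; and transit fixes emitted along any hop that spans more
than one interval at the 12 km h⁻¹ flight speed, so they are removable by
the speed filter. Scales follow the field values the analysis was designed
around: ~20 m within-segment step medians (reported range 12–27 m),
0.5–1.3 km entry steps, a few patches per day, and an excess of short
segments driven by the disturbance process. All draws come from one
`numpy` Generator; `simulate_population` is byte-deterministic under its
seed.

What the generator does *not* emulate: GPS position error as a separate
noise layer (the 10 m buffer is still applied downstream), battery-saver
6 h gaps, molt/nesting/brooding life-history phases, migration legs,
habitat selection, and inter-individual heterogeneity. Passing recovery
tests therefore demonstrate that the pipeline's operations invert the
generative process they assume — segment/patch/revisit recovery, decay
recovery, break-point betweenness — not that real duck data meet those
assumptions.

## Numerical and testing choices

Repetition studies derive per-dataset seeds by `SeedSequence` spawning
from one master seed, mirroring the acceptance script's single `--seed`.
The end-to-end recovery study uses 500 bird days (25 birds × 20 days),
enough to pin the decay slopes to ±0.002 while keeping the suite fast; the
NN-CC calibration study uses 100 datasets × 1000 permutations. Note the
mean-p calibration check has an irreducible SE of ~0.03 at 100 datasets
(each null p is uniform), so its ±0.05 band is a ~1.7σ criterion.
Degenerate inputs are defined rather than crashed on: < 2 fixes → empty
step table; all-zero steps → error; < 3 patches or coincident centres →
SCI absent; < 5 values → median without CI. Known limitations: solar times
assume |lat| < 66°; the density break point requires genuinely bimodal
step structure (unimodal data returns a failure flag, not a number); and
the bridged-distance convention after flight removal slightly understates
true path length when a removed transit fix was far off the bridge line.
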