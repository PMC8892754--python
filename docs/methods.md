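# Methods

## Scope and model of the data

The package analyzes migratory GPS tracks of fly-and-forage waterbirds:
multi-day journeys sampled every 5 min – 2 h, resampled to 30-min intervals,
over landscapes where aquatic foraging habitat (open water and permanent
wetlands) varies from absent (desert) to ubiquitous (open sea). Positions
are WGS84 lon/lat; all distances are great-circle on a sphere of radius
6371 km (haversine). At step scales of a few to a few hundred km the error
against an ellipsoid is below 0.5%, which is negligible relative to GPS and
classification noise.

## Track processing

**Quality filter.** Fixes implying ground speed > 150 km/h or |climb rate|
> 20 m/s against the previous retained fix are removed one worst offender at
a time until none remain. One-at-a-time removal matters: a single spike fix
corrupts both its inbound and outbound steps, and batch removal would also
delete the innocent neighbor. The thresholds are configuration, chosen as
generous physical limits for a large flapping bird.

**Resampling.** For each 30-min slot the nearest observed fix within a
5-min tolerance is kept. Positions are never interpolated: fabricated
positions would feed fabricated speeds into the flight classifier.
Resampling an already-30-min track is the identity.

**Flight classification.** A 30-min interval is migratory flight iff the
instantaneous ground speed exceeds 10 km/h at *both* endpoints, with strict
inequality (10.0 km/h exactly is stationary). The device-reported
instantaneous speed is used when present; otherwise the speed of the step
ending at the fix stands in. This rule cannot represent a single stationary
interval inside a flight bout (both of its endpoints still move); the
synthetic generator therefore never emits one — an identifiability
constraint of the rule, not a physical claim.

**Solar phase.** Sunrise/sunset from the NOAA low-precision solar algorithm
at elevation −0.833° (accuracy ~1–2 min; phases are decided at hour scale).
`dawn_dusk` is within ±1 h of either event; daylight + dark = 24 h per
date/location. Polar day/night force the phase and use 24/0 h.

## Segmentation

A day is a stopover day when the net displacement between last daily
relocations is ≤ 35 km (inclusive at the boundary; the criterion is net
advance, not path length). Calendar days are UTC by default — the choice is
exposed because for east–west migrations local solar days could split days
differently. Days without fixes inherit the preceding day's classification,
which avoids spurious segment breaks at battery gaps. Stopovers are maximal
runs of such days; traveling segments are the maximal complementary runs and
carry two covariates: days-of-migration (days since track start) and
days-at-previous-stopover (duration of the immediately preceding stopover;
for the first autumn segment the pre-departure staging duration supplied as
metadata; undefined in spring, where fuelling happens inside the wintering
range). Region labels come from user-editable GeoJSON polygons by majority
of member fixes — a reproducible replacement for manual assignment.

## Behavior metrics

- **Travel speed**: cumulative path length over consecutive resampled fixes
  ÷ number of segment days.
- **Flight height agl**: GPS altitude − bilinear DEM elevation, for
  flight-classified fixes only; summarized by the **median** (robust to GPS
  altitude spikes); negative heights are retained because discarding them
  would bias low flights upward.
- **Daily flight hours**: 0.5 h per flight interval, averaged over days.
- **Day/night flight ratio**: per day,
  `(day flight h / daylight h) / (night flight h / dark h)`; > 1 means
  disproportionately diurnal flight after correcting for photoperiod.
  Dawn/dusk flight is apportioned to day or night by the sun's side of the
  horizon at the interval midpoint. Zero day- or night-flight hours are
  replaced by 0.25 h (half an interval) — a continuity correction that keeps
  per-day ratios finite; its magnitude is configuration. Days with no
  daylight or no darkness are excluded.
- **Straightness**: beeline distance ÷ path length, in (0, 1]; 1 iff motion
  is monotone along a great circle. (The index is sometimes verbally stated
  inverted in the literature; values must lie below 1, which fixes the
  orientation.)
- **Percent change**: 100 × (value − individual seasonal mean) / mean;
  within-individual variation with a −100% lower bound for non-negative
  metrics.

## Environmental annotation

Altitude maps to pressure via the ISA troposphere formula
`p = 1013.25 (1 − 0.0065 h / 288.15)^5.256` and the nearest of the eight
standard levels (1000…300 mb) is used. Fields are interpolated bilinearly in
lon/lat; wind (u, v) additionally linearly in time between 6-h steps;
non-wind variables are joined only at fixes on the synoptic hours
(00/06/12/18 UTC), so no temporal extrapolation of slowly sampled fields is
invented.

Wind support: with y = √(u²+v²) and θ the angle between the track bearing
and the direction the wind blows **toward**, tailwind `fa = y cos θ` (signed
support along track) and crosswind `y sin θ`, positive for wind from the
bird's left; magnitude-only is available since analyses differ on whether
crosswind enters signed or absolute. `fa² + cross² = y²` holds identically.

Water overlap: the segment polyline is buffered 5 km each side in an
azimuthal-equidistant projection centered on the segment (metrically
correct at any latitude); the proportion is aquatic pixels ÷ all pixels
whose centers fall inside the buffer. The same disc logic, with a 5 km
radius, gives per-point proportions for the selection test.

## Habitat-selection randomization test

For each relocation, 99 points uniform by area (radius R√U, uniform
bearing) in a geodesic disc of 35/50/80 km — radii bracketing the horizon
range √(2·6371·h) of a bird a few hundred meters up (≈80 km at 500 m). The
one-tailed Monte-Carlo p-value uses the add-one rank rule
`p = (1 + #{null ≥ obs}) / 100`, ties counted against the observation
(conservative); p < 0.05 therefore requires the observation to beat at
least 96 of 99 nulls, an exact level-0.04 test under exchangeability.
Per-relocation RNG streams derive from (master seed, relocation index), so
results are order-independent and reproducible. Relocations whose 99 nulls
all equal the observed value (fully homogeneous surroundings — open sea,
bare desert) are excluded from summaries. Daily summaries count 0.5 h per
significant fix, stratified by solar phase × activity (flight vs
stationary); the binomial GLMM stage (proportion significant ~
phase × activity + (1 | individual)) is delegated to statsmodels'
Bayesian binomial mixed GLM, with this module owning the data preparation.

For bulk evaluation the per-point disc proportion is precomputed by
convolving the water mask with a disc kernel once and sampling the smoothed
field bilinearly; it agrees with exact pixel counting to < 0.02 away from
raster edges and makes 10⁶ point queries trivial. Exact counting remains
the reference implementation and the oracle in tests.

## Mixed-effects inference

Numeric predictors are centered and scaled to one sample SD. Collinearity
is screened by iteratively dropping the worst-VIF predictor while any
tolerance (1/VIF) is below 0.20; domain overrides can protect a named
variable of a correlated pair (default: air temperature over surface
temperature, as the more flight-relevant of the two). Responses are Box–Cox
transformed with λ maximized over a −2…2 grid (step 0.01), with a recorded
positive shift for zero-containing responses.

Mixed models are fit with statsmodels MixedLM. An individual-only random
intercept uses the native grouping; richer structures (colony, year,
segment nested in individual) are expressed as variance components under a
single constant group — an equivalent parameterization of crossed/nested
intercepts. A fit is singular when any random-effect variance falls below
10⁻⁶ of the residual variance. The random structure is chosen as the
lowest-AICc non-singular REML fit, falling back to individual-only. The
optimizer falls back from lbfgs to powell/cg when the profiled likelihood
is non-finite at a variance boundary (a known lbfgs failure mode).

All 2^p fixed-effect subsets (guarded at p ≤ 20) are fit by ML so that
AICc = AIC + 2k(k+1)/(n−k−1) and BIC are comparable; Akaike weights are
`exp(−Δ/2)` renormalized. Averaging uses the smallest set reaching 95%
cumulative weight, renormalized; the **zero method** sets a predictor's
coefficient to 0 in models excluding it, which shrinks weakly supported
effects toward zero (the averaged magnitude never exceeds the
natural-method magnitude). Unconditional SE:
`sqrt(Σ w (se² + (β − β̄)²))`; 95% CI = estimate ± 1.96 SE, and a predictor
is "distinguishable" when that CI excludes 0. Both AICc and BIC are
exposed; BIC yields smaller confidence sets on these data. Likelihood-ratio
tests compare nested ML fits via χ² = 2Δℓ with df = Δk.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions end to end: multi-day tracks at
5–120 min cadence with implanted stopover schedules (days of negligible net
displacement), per-interval flight drawn from day/night probabilities, a
constant compass heading, daily distance
`cruise_speed × flight hours + β_water × w + intercept + noise` where w is
the local 5 km aquatic proportion (β_water is the recoverable ground-truth
habitat effect), GPS altitude = DEM + sampled height agl with optional
Gaussian noise (default sd 15 m in configs) and gross-error spikes,
landscapes at MODIS-like 500 m resolution with uniform-random, corridor or
smoothed-noise patch patterns (aquatic pixels split between wetland 11 and
water 17), and 6-hourly 2.5° pressure-level weather with zero, constant or
rotating wind.

Deliberate simplifications: constant heading (real routes curve, so
straightness ≈ 1 by construction and the straightness tests are geometric,
not behavioral); the habitat effect enters daily distance linearly; wind
does not displace the bird (no drift dynamics); landscapes are statistical
patterns, not real geography. Passing tests therefore demonstrate that the
*estimators* recover known structure, not that real birds behave this way.

The selection benchmark scene deserves a note: a single water corridor
alone would make the significant fraction *rise* with buffer radius
(distant nulls are poorer). The declining pattern arises when larger
availability radii reach other rich habitat, so the benchmark places a
30 km "sea" with its near edge 45 km from the corridor — inside the 50 and
80 km buffers but outside 35 km — over ~10% total water. Power at 35 km and
the monotone decline across 35→50→80 km are then structural properties of
the scene.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script: 50 tracks × 11
days for stopover recovery; 10⁴ relocations × 99 nulls for calibration
(via the convolution sampler); 60 corridor relocations × 3 buffers; 100
replicates of 20 individuals × 10 segments (β_water = −200 km/day,
individual sd 30, residual sd 50) for coverage — sizes at which every
Monte-Carlo band in the tests is comfortably resolved. Ties in the rank
test count as ≥; Box–Cox λ ties resolve to the first grid maximum;
zero-length steps have undefined bearing and receive no wind annotation;
discs partially outside a raster are evaluated on the intersection and
flagged.

## Known limitations

- Crossed random effects via variance components refit the full design per
  candidate structure; fine at these sizes, slow for thousands of groups.
- The binomial GLMM for selection summaries is variational Bayes
  (statsmodels), not Laplace/adaptive-quadrature ML; treat its intervals as
  approximate.
- The solar algorithm degrades near the poles (phases are forced under
  polar day/night) and the 1-h dawn/dusk window is a convention.
- UTC calendar days bias day boundaries for strongly east–west migrations;
  use the configurable local-day option there.
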