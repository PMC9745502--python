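# Methods

This note documents the models, parameter choices and numerical decisions
behind `tuckmolt`, and what the simulation-based tests do and do not
demonstrate about real logger data.

## Solar geometry

`tuckmolt.solar` implements the NOAA (Meeus-derived) low-precision solar
ephemeris: apparent declination and equation of time from the Julian century,
elevation from the hour angle, with the NOAA atmospheric refraction
correction available (on by default, ~0.5° at the horizon, zero above 85°).
Accuracy is a few hundredths of a degree over 1950–2050, which is far inside
the tolerances that matter here — the behavioral gates at −6° and −3°
elevation. The test suite cross-checks against the Spencer (1971) Fourier
series, an independent derivation good to ~0.3°.

Threshold geolocation works on *geometric* (unrefracted) elevations
throughout: the calibrated zenith absorbs refraction, atmospheric
attenuation and the sensor's threshold response in a single constant.
Elevations for behavioral gating use the refracted value at the smoothed
daily position of the fix's calendar day; a missing day falls back to the
nearest available day. Daily assignment (rather than interpolation) is the
coarsest choice consistent with the ≤ 2 positions/day that threshold
geolocation yields.

## Threshold geolocation

**Twilights.** A twilight is a crossing of raw light level 1 (on the 0–64
scale) that bounds a *sustained* dark period: a below-threshold run must last
at least 4 h to count as night (`min_dark_hours`), and nights separated by
less than 2 h of light are merged (`min_light_hours`). Without the
sustained-darkness requirement every daylight tucking bout becomes a
spurious sunset/sunrise pair — on simulated data, naive crossing detection
finds ~35× more "twilights" than there are real ones, far beyond what the
downstream editor can repair. Crossing times are linearly interpolated
between the bracketing fixes.

**Editing.** An event whose time-of-day deviates > 45 min
(`outlier_mins`) from the median of same-kind events within ±4 days
(`window`) is adjusted to that median when those neighbours agree within
15 min (`stationary_mins`) — a stationary bird, so the outlier is an
artifact such as an evening tuck bout that merged into the night — and
deleted otherwise (possibly genuine movement, but unusable). These editing
constants are explicit knobs; they were chosen once as round values on the
scale of twilight noise and are not tuned per dataset.

**Positions.** Longitude comes from the midpoint of a sunrise/sunset pair
against true solar noon; the equation of time is included (omitting it
biases longitude by up to ±4°). Latitude inverts
`sin(alt0) = sin φ sin δ + cos φ cos δ cos H` for the calibrated zenith,
with `H` half the day length in degrees. Day lengths that admit no solution
(equinox degeneracy, or geometry impossible at that zenith) yield an
undefined latitude; when both roots of the inversion lie in [−90°, 90°]
(possible only near the equinox) the equatorward root is taken — those
latitudes are overwritten by the equinox smoother anyway. One fix is kept
per calendar day of the pair's midpoint.

**Zenith calibration.** A wrong zenith turns the seasonal declination cycle
into spurious latitude drift, fastest near the equinoxes. For each candidate
zenith (90°–100° in 0.25° steps) the full latitude series is computed; the
objective is the *median over centred 21-day windows of the within-window
latitude variance*, evaluated only on days whose latitude is defined for
every candidate, plus 10 deg² per unit fraction of undefined latitudes.
Within-window variance is variance about a locally-constant trend, so
genuine migration (slow, between windows) contributes little while
wrong-zenith drift (fast, within windows) dominates. The common-support
restriction matters: without it, larger zeniths win by pushing their
diverging equinox latitudes into "undefined" and silently deleting the
evidence against them. Ties go to the smaller zenith. Calibration fails when
every candidate leaves > 50% of latitudes undefined or tens of degrees of
within-window scatter (objective > 400 deg²): the twilight series carries no
zenith signal.

**Equinox smoothing.** Latitudes in the two-month windows Aug 22–Oct 23 and
Feb 19–Apr 22 are replaced by a LOESS fit over date (local linear,
span 0.3 — wide enough to kill equinox noise while tracking monthly-scale
movement); inside the core windows Sep 1–Oct 13 and Mar 1–Apr 12 they are
then replaced by linear interpolation between the smoothed values at the
core-window edges. Longitudes are never touched.

**Residency segmentation.** The daily great-circle distance to the colony
(haversine, spherical Earth R = 6371 km; sub-0.5% error is negligible at
geolocator accuracy) is segmented by penalised least squares: dynamic
programming gives the optimal K-segmentation for each K with a minimum
segment length of 7 days; K is chosen by Lavielle's rule — the largest K
whose normalised-contrast second difference exceeds 0.75 — with a
no-structure guard (one segment when the first changepoint fails to explain
at least half of the contrast; pure noise otherwise "earns" segments through
min-length overfitting). Migratory effort is the most distant segment's mean
colony distance and duration.

## Leg-tuck correction

Raw light is scaled to [0, 1] (÷64) and modelled against solar elevation by
isotonic regression — monotone nondecreasing least squares — on a uniform
random subset of at most 100,000 fixes (seeded, so refits are identical).
Monotonicity is the physically meaningful constraint; the fit is piecewise
constant with linear interpolation between knots and is clipped to [0, 1].
`residual_sd` is the SD of observed minus predicted over the fitted subset —
a single global value, since the flagging rule is stated in terms of one SD,
not a heteroscedastic band.

A fix is flagged as tucking when all of:

* solar elevation > −6° (below that, expected light is zero and a dark
  logger carries no information — night fixes are `not_assessable_night`);
* predicted − observed > 2 × `residual_sd`;
* predicted − 2 × `residual_sd` > 0.02 (a floor that keeps the rule from
  firing vacuously near twilight where the 2-SD band reaches zero).

The single fix before and after each maximal flagged run is flagged too
(`tucked_neighbor`): at the edges of a bout the fix's *maximum* light is not
anomalous, but part of the interval was still tucked. Immersion bins are set
fully wet (scale 200) when any flagged light fix interval overlaps them —
with 5-min light against 10-min immersion, one flagged fix wets one bin.
The correction is monotone (wet counts never decrease) and idempotent.

## Dual-logger fusion

The finer-interval series is the merge base; each base record is paired with
the nearest other-logger record, compared as *proportions* of each series'
scale (so mixed 5/10-min deployments are comparable), and the higher wet
proportion retained. A partner further than half the other's fix interval is
treated as absent (stale values must not bridge recording gaps) and the base
value stands. Fusion is run in both directions and molt detection reported
on each basis, because the nearest-timestamp merge is not symmetric; the
per-bird report gives start/duration ranges across the two bases. Fusion can
only overestimate wetness — acceptable, since any immersion at all excludes
sustained flight.

## Molt detection

`prop_flight` is the corrected proportion of time dry per UTC calendar day
over immersion bins with solar elevation > −3°. The −3° gate (rather than
−6°) excludes twilight/night bins where sustained dry spells are dominated
by both-leg tucking and burrow visits, which no single-logger light
correction can see. `prop_flight5` is the 5-day centred mean, defined when
at least 3 of the 5 days are defined.

The detector increments a threshold from 0 in steps of 0.0002 until some run
of ≥ 30 consecutive days has every defined day's `prop_flight5` strictly
below it, capped at 0.01: longer spells of merely *reduced* flight
(voluntary residency in good conditions) must not be read as molt. The
longest run at the terminating threshold (earliest on ties) is the window's
*core*; the reported window is the core extended over the surrounding
consecutive days whose `prop_flight5` stays below the cap — the flightless
period is the continuous sub-1% spell anchored on a persistently low core.
Without the extension, any realistic nonzero dry floor truncates long molts:
the first threshold that admits one 30-day run sits at the floor's order
statistics and cuts the run at the first noise day. Runs may not bridge an
excluded date range nor a gap of ≥ 3 consecutive undefined days (logger
outages must not manufacture 30-day runs), and must start and end on defined
days. The scan is repeated once with the first window's dates excluded; at
most two windows are reported, labelled with the iteration that found them.

Strict comparison ("below" = `<`) makes a run of exact zeros detectable at
the very first increment; a threshold of 0 can never flag anything.

Analysis is restricted to the non-breeding season (default Aug 1 – Apr 30):
summer burrow attendance mimics dryness. Calendar days are UTC throughout —
local-solar-day offsets are far below the 5-day smoothing scale.

## The behavior simulator

The generator produces a per-minute ground-truth trace for one bird over a
deployment (default 2010-08-01 to 2011-04-30, colony at Skomer-like
51.737° N 5.297° W, migration to two mid-Atlantic residency waypoints at
500 km/day) and renders it to the loggers' native formats. Its defaults are
the study conditions for every simulation-based test:

* **Daily daylight flight fraction**: Normal(1.9%, SD 5.8%) truncated to
  [0, 1], drawn per day; forced to 0 inside inserted molt windows. Flight
  bouts are exponential (mean 45 min — winter commuting/foraging flights are
  tens of minutes, and much shorter bouts would be artificially erased by
  the bin-level wet correction).
* **Daily daylight tuck fraction**: Beta moment-matched to mean 21.7%,
  SD 20.1% (a truncated normal cannot hold that mean — its realised mean
  would be ~27%). Tuck bouts are lognormal (median 20 min, σ = 0.6, minimum
  10 min) with a 10-min inter-bout guard: bout structure must come from the
  length distribution, not from packing artifacts (sub-fix fragments and
  back-to-back opposite-leg bouts are measurement-model artifacts, not
  behavior). Days drawn mostly-tucked (> 50% of free daylight) are realised
  as continuous rafting spells. A daylight bout involves both legs with
  probability 0.02 — field observation is "usually just one at a time" —
  otherwise one leg at random.
* **Night tucking**: 35% of deep-night time (solar elevation < −9°), 70% of
  bouts both-leg. Twilight hours are left active: auks paddle and forage
  around dusk/dawn, and deep-night confinement also means equinox position
  error cannot sweep genuinely dark both-tucked bins into the −3° daylight
  gate.
* **Dives**: ~10% of daylight as ≤ 2-min events, wet, placed after tucking
  (scattering single minutes first would fragment the surface runs tuck
  bouts need).
* **Dry-blip floor**: 0.1% of surface time is dry on both legs in brief
  3-s moments (preening, posture) — the floor that keeps flightless-period
  dry time near, not at, zero, matching the ~0.1% dual-combined dry time
  the method measures during molt.
* **Burrow visits**: after Mar 20, nightly with probability 0.5, 1–4 h, dry
  and dark.
* **Rendering**: per-minute ambient light is logistic in solar elevation
  (midpoint −3°, scale 0.75°), so the level-1 crossing sits near civil
  twilight (−6°) — consistent with what the 6-bit logger scale encodes
  (0 = below civil twilight). A daily cloud factor U(0.7, 1.0) and
  signal-dependent sensor noise (SD 0.5 units at mid-scale, a solid 0 in the
  dark) provide realistic scatter. A single-leg tuck bout is fully opaque
  with probability 0.7, otherwise translucent (attenuation U(0.4, 0.9)) — a
  loose tuck is the main way real tucking escapes light-based detection;
  both-leg bouts are a deep-rest posture and always opaque. Immersion is
  wet when the bird is on water or diving and the leg is untucked, counted
  in 3-s samples per 10-min bin.

The bout-level parameters (lengths, opacity, both-leg shares, the dry-blip
floor) are not published quantities; they were fixed once by requiring the
renderer to reproduce the *measured* properties this class of deployment
reports — a raw → light-adjusted → dual-combined daylight dry-time ladder of
roughly 12–15% → 5–7% → 2–4.5%, single-leg dry time of a few percent during
flightless spells versus ~0.1% dual-combined — and then frozen.

**What the simulator does not emulate**: weather-driven twilight anomalies
beyond daily cloud, logger clock drift, mid-deployment failures, shading by
the bird's own body in flight, latitude-dependent tucking behavior, and any
energetic feedback between molt and activity. Passing the simulation suite
therefore shows the chain is correct *under the measurement model described
here*; on real data the main additional risks are clock drift (not
corrected) and behavior whose bout structure differs from the lognormal
defaults.

## Accuracy under the default conditions

The acceptance suite (`tests/test_acceptance.py`, reproducible via
`scripts/acceptance.py`) runs 100 dual-equipped birds with one inserted
30–60-day flightless window each and 100 birds without any. Under those
conditions the dual-logger chain recovers ≥ 90% of windows with both
boundaries within 3 days, reports zero windows on molt-free birds, and the
dry-time ladder ordering holds on every bird tucking ≥ 10%. Single-logger
detection is far rarer than dual detection at the default ~22% tucking rate
— residual one-leg tucking keeps molt-period dry time above the 1% cap —
mirroring the sharp dual/single sensitivity gap this method shows on real
deployments. A second inserted 32-day window in February is recovered in
roughly a quarter of replicates: its clean interior (28 days) is shorter
than the 30-day minimum, so recovery depends on calm boundary days. The
threshold scan itself agrees with an exhaustive brute-force oracle on 1,000
random 240-day series, and forward-simulated twilights invert to within
0.5° longitude / 1° latitude (outside equinox windows) with zenith
calibration within 0.5°.

## Known limitations

* Nocturnal both-leg tucking is invisible to the light correction by
  construction (expected light is zero below −6°); the −3° activity gate
  excludes it rather than correcting it.
* A detected window is "flightless", not "molting": voluntary flightless
  residency cannot be distinguished from primary molt by immersion alone.
* Single-logger mode is conservative by design; its non-detections are
  weak evidence of absence.
* Latitude quality collapses near the equinoxes — exactly when first molts
  tend to occur — so molt *locations* inherit the smoothed-latitude
  uncertainty.
* No clock-drift correction is applied over the ~10-month deployments.
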