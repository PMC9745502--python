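# tuckmolt

Flightless-molt detection for alcids from leg-mounted geolocator/immersion
loggers, with correction of the leg-tucking artifact.

Larger auks (puffins, murres, razorbills) replace all primary flight feathers
at once and are flightless for weeks during the non-breeding season. A
leg-mounted saltwater-immersion logger should reveal such periods as weeks of
near-continuous wet readings — except that these birds routinely tuck one leg
(sometimes both) into their plumage while resting on the water, so the logger
reads *dry and dark* while the bird is sitting at sea. `tuckmolt` implements a
processing chain that defeats this confound and identifies flightless windows:

1. **Threshold geolocation** (`tuckmolt.geolocate`): twilights where raw light
   crosses level 1 on the 0–64 logger scale, a moving-window twilight editor,
   Hills–Ekstrom solar-zenith calibration, longitude from the twilight
   midpoint and latitude from day length, LOESS/linear smoothing of equinox
   latitudes, and Lavielle changepoint segmentation of the daily
   colony-distance series.
2. **Leg-tuck correction** (`tuckmolt.tuck_correct`): scaled light (raw/64) is
   modelled against solar elevation by monotone (isotonic) regression on a
   100,000-fix subset; a daylight fix (solar elevation > −6°) whose reading
   falls more than 2 residual SD below the prediction is classified as
   tucking, the fix on either side of each tucked run is classified as
   tucking too, and the overlapping immersion bins are set fully wet (200).
3. **Dual-logger fusion** (`tuckmolt.dual_combine`): for birds carrying a
   logger on each leg, wet proportions are merged to the nearest timestamp
   and the *higher* value retained — if either leg was submerged the bird was
   on the water.
4. **Molt detection** (`tuckmolt.molt_detect`): the corrected proportion of
   daylight (solar elevation > −3°) time dry per day is taken as flight time
   (`prop_flight`); its 5-day centred mean (`prop_flight5`) is scanned with a
   threshold incremented from 0 in steps of 0.0002 (capped at 1%) until a run
   of ≥ 30 consecutive days falls below it; the reported window is that run
   extended over the surrounding days that stay below the 1% cap. The scan is
   repeated once with the first window excluded, allowing a second molt.
5. **Behavior simulator** (`tuckmolt.simulate`): generates ground-truth
   puffin-like behavior (migration, flight/dive/tuck/burrow bouts, inserted
   flightless windows) and renders it to the exact raw streams the loggers
   record — 6-bit max light per 5/10-min fix and 3-s wet counts (0–200) per
   10-min bin — so every stage above can be scored against known truth.

The package is aimed at movement ecologists working with archival
geolocator/immersion tags (BAS/Biotrack/Lotek-style Mk loggers) on diving
seabirds.

## Worked example

Simulate a dual-equipped bird with a flightless window inserted from
2010-09-15 to 2010-10-24 (40 days), then run the full dual-logger chain:

```sh
tuckmolt simulate --seed 3 --out sim
tuckmolt run \
  --light-left sim/light_left.csv  --immersion-left sim/immersion_left.csv \
  --light-right sim/light_right.csv --immersion-right sim/immersion_right.csv \
  --colony 51.737 -5.297 --out report
```

which prints

```
daylight dry time: raw 14.8% / light_adjusted 6.4% / combined 4.3%
 iteration  n_bases  start_min  start_max  duration_min  duration_max
         1        2 2010-09-16 2010-09-16            38            38
```

The first line is the diagnostic ladder: of daylight time, the raw immersion
signal reads 14.8% dry (flight *plus* tucking artifacts), the light-based
correction removes the detectable tucking (6.4%), and fusing both legs
removes most of the rest (4.3%, approaching the bird's true flight time).
The table reports the detected molt window on each fusion basis (left- and
right-based merges can differ slightly, hence ranges): here both bases find
one window starting 2010-09-16 lasting 38 days — one day inside the inserted
truth at each boundary. Per-basis daily activity, positions and molt CSVs are
written under `report/`.

The same chain runs on standard single-logger deployments (`--single`, or
omit the right-leg files); single-logger detection is markedly less sensitive
because tucking on the logger leg cannot be cross-checked against the other
leg.

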