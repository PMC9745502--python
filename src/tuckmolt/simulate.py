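"""Behavioral simulator for leg-mounted geolocator/immersion loggers.

Generates a ground-truth activity trace for a puffin-like alcid over a
non-breeding season — migration between residency waypoints, daily flight and
dive bouts, leg-tuck bouts on the water (one leg, the other, or both; both
legs preferentially at night), burrow visits approaching the breeding season,
and inserted flightless molt windows during which flight is forced to zero —
then renders the trace to the raw data streams the loggers would record: 6-bit
max-light per 5- or 10-min fix and 3-s wet counts per 10-min bin.

Daily daylight activity budgets follow the field-observed values for Atlantic
puffins: flight centred on 1.9% of daylight (SD 5.8) and leg tucking 21.7%
(SD 20.1).  Daily flight fractions are truncated-normal draws; tuck fractions
are Beta draws moment-matched to the observed mean/SD (a Gaussian truncated
at zero cannot hold that mean).  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .geo_io import ImmersionSeries, LightSeries

logger = logging.getLogger(__name__)

# per-minute behavioral state codes
SURFACE, FLIGHT, DIVE, BURROW = 0, 1, 2, 3
STATE_LABELS = {SURFACE: "surface", FLIGHT: "flight", DIVE: "dive", BURROW: "burrow"}
# per-minute tuck codes (only on SURFACE minutes)
NO_TUCK, TUCK_LEFT, TUCK_RIGHT, TUCK_BOTH = 0, 1, 2, 3

DAYLIGHT_DEG = -3.0


@dataclass(frozen=True)
class Waypoint:
    lat: float
    lon: float
    residency_days: int


@dataclass(frozen=True)
class RenderParams:
    """Knobs of the light/immersion renderer.

    The ambient curve is logistic in solar elevation (midpoint -3 deg, scale
    0.75 deg) so that the geolocation threshold of 1 on the 0-64 scale is
    crossed near civil twilight (-6 deg), matching what the loggers' 6-bit
    scale encodes (0 = below civil twilight).  Daily cloud attenuation and per-bout tuck
    opacity emulate the two reasons real tucking partially escapes light-based
    detection: weather scatter inflates the model residual SD, and a loosely
    tucked leg is not fully darkened.
    """

    light_midpoint_deg: float = -3.0
    light_scale_deg: float = 0.75
    cloud_range: tuple[float, float] = (0.7, 1.0)   # daily multiplicative attenuation
    noise_sd: float = 0.5                           # per-minute additive noise, 0-64 units
    tuck_opacity_prob: float = 0.7                  # fraction of single-leg tuck bouts fully dark
    translucent_range: tuple[float, float] = (0.4, 0.9)


@dataclass(frozen=True)
class BehaviorParams:
    """Ground-truth behavioral scenario (defaults: one Skomer-like season)."""

    start: str = "2010-08-01"
    end: str = "2011-04-30"
    colony: tuple[float, float] = (51.737, -5.297)
    waypoints: tuple[Waypoint, ...] = (Waypoint(52.0, -22.0, 60),
                                       Waypoint(47.0, -30.0, 110))
    travel_speed_km_day: float = 500.0
    flight_frac_mean: float = 0.019
    flight_frac_sd: float = 0.058
    tuck_frac_mean: float = 0.217
    tuck_frac_sd: float = 0.201
    p_both_tuck_day: float = 0.02
    night_tuck_frac: float = 0.35
    night_tuck_sd: float = 0.20
    p_both_tuck_night: float = 0.70
    night_tuck_max_elevation: float = -9.0  # tucking happens in deep night; twilight is active time
    tuck_bout_median_min: float = 20.0
    tuck_bout_sigma: float = 0.6       # lognormal sigma of bout length
    tuck_bout_min_min: int = 10        # shortest tuck bout the generator places
    flight_bout_mean_min: float = 45.0
    dive_frac: float = 0.10
    preen_dry_frac: float = 0.001     # fraction of surface time dry in brief (3-s) moments
    burrow_window_start: tuple[int, int] = (3, 20)  # (month, day)
    burrow_visit_prob: float = 0.5
    burrow_bout_min: tuple[float, float] = (60.0, 240.0)
    molt_windows: tuple[tuple[str, int], ...] = (("2010-09-15", 40),)
    render: RenderParams = field(default_factory=RenderParams)
    seed: int = 0

    def molt_ranges(self) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
        out = []
        for start, dur in self.molt_windows:
            s = pd.Timestamp(start).normalize()
            out.append((s, s + pd.Timedelta(days=int(dur) - 1)))
        return out


@dataclass
class BehaviorTrace:
    """Per-minute ground-truth trace plus daily positions."""

    minutes: pd.DatetimeIndex        # minute start times, UTC
    state: np.ndarray                # int8 state codes
    tuck: np.ndarray                 # int8 tuck codes
    elevation: np.ndarray            # solar elevation at the day's true position
    positions: pd.DataFrame          # date, lat, lon
    params: BehaviorParams
    dry_blip: np.ndarray | None = None   # dry 3-s samples per surface minute (both legs)

    @property
    def day_index(self) -> np.ndarray:
        return np.arange(len(self.minutes)) // 1440

    def intervals(self) -> pd.DataFrame:
        """Run-length encoding to contiguous (start, end, state) intervals."""
        code = self.state.astype(int) * 10 + self.tuck.astype(int)
        change = np.flatnonzero(np.diff(code)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(code)]])
        labels = []
        for s in starts:
            st, tk = self.state[s], self.tuck[s]
            if st == SURFACE and tk != NO_TUCK:
                suffix = {TUCK_LEFT: "left", TUCK_RIGHT: "right", TUCK_BOTH: "both"}[tk]
                labels.append(f"surface_tuck_{suffix}")
            else:
                labels.append(STATE_LABELS[int(st)])
        return pd.DataFrame({
            "start": self.minutes[starts],
            "end": self.minutes[ends - 1] + pd.Timedelta(minutes=1),
            "state": labels,
        })


def _slerp(p0: tuple[float, float], p1: tuple[float, float], f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Great-circle interpolation between two (lat, lon) points, f in [0,1]."""
    def to_vec(lat, lon):
        la, lo = np.radians(lat), np.radians(lon)
        return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])
    v0, v1 = to_vec(*p0), to_vec(*p1)
    omega = np.arccos(np.clip(v0 @ v1, -1, 1))
    f = np.asarray(f, dtype=float)
    if omega < 1e-9:
        v = np.outer(np.ones_like(f), v0)
    else:
        v = (np.outer(np.sin((1 - f) * omega), v0) + np.outer(np.sin(f * omega), v1)) / np.sin(omega)
    lat = np.degrees(np.arcsin(np.clip(v[:, 2], -1, 1)))
    lon = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    return lat, lon


def _gc_km(p0, p1) -> float:
    la0, lo0, la1, lo1 = map(np.radians, (p0[0], p0[1], p1[0], p1[1]))
    a = np.sin((la1 - la0) / 2) ** 2 + np.cos(la0) * np.cos(la1) * np.sin((lo1 - lo0) / 2) ** 2
    return float(6371.0 * 2 * np.arcsin(np.sqrt(a)))


def simulate_track(params: BehaviorParams) -> pd.DataFrame:
    """Daily positions: piecewise great-circle travel between residency waypoints.

    The bird leaves the colony, visits each waypoint in order (travelling at
    ``travel_speed_km_day``, then resident for the waypoint's duration),
    returns to the colony, and stays there for any remaining days.  Truncated
    at the deployment end if the itinerary is longer than the span.
    """
    dates = pd.date_range(pd.Timestamp(params.start).normalize(),
                          pd.Timestamp(params.end).normalize(), freq="D")
    n = len(dates)
    lats = np.full(n, params.colony[0])
    lons = np.full(n, params.colony[1])
    day = 0
    here = params.colony
    legs = list(params.waypoints) + [Waypoint(params.colony[0], params.colony[1], 10**6)]
    for wp in legs:
        dest = (wp.lat, wp.lon)
        travel = int(np.ceil(_gc_km(here, dest) / params.travel_speed_km_day))
        for t in range(travel):
            if day >= n:
                break
            la, lo = _slerp(here, dest, np.array([(t + 1) / travel]))
            lats[day], lons[day] = la[0], lo[0]
            day += 1
        here = dest
        for _ in range(int(wp.residency_days)):
            if day >= n:
                break
            lats[day], lons[day] = here
            day += 1
        if day >= n:
            break
    return pd.DataFrame({"date": dates, "lat": lats, "lon": lons})


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched Beta(a, b); SD shrunk if infeasible for the mean."""
    mean = float(np.clip(mean, 1e-6, 1 - 1e-6))
    var = min(sd * sd, 0.95 * mean * (1 - mean))
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def _place_bouts(rng: np.random.Generator, free: np.ndarray, target: int,
                 length_fn, min_bout: int = 5, guard: int = 0,
                 max_attempts: int = 200) -> list[np.ndarray]:
    """Fill ~``target`` minutes of ``free`` with contiguous bouts.

    Bouts are placed inside free runs (run chosen with probability
    proportional to its length, start uniform within it), never shorter than
    ``min_bout`` unless the run itself is shorter — bout structure should
    come from the length distribution, not from packing artifacts.  A
    ``guard`` of n minutes on each side of a placed bout is blocked without
    being assigned, so bouts do not abut back-to-back.  Stops within
    ``min_bout`` of the target.  ``free`` is mutated; returns per-bout index
    arrays.
    """
    bouts: list[np.ndarray] = []
    placed = 0
    attempts = 0
    n = len(free)
    # a target below min_bout becomes one min_bout bout with probability
    # target/min_bout: expected total stays unbiased with no short fragments
    if 0 < target < min_bout:
        target = min_bout if rng.random() < target / min_bout else 0
    while placed + min_bout <= target and attempts < max_attempts:
        attempts += 1
        idx = np.flatnonzero(free)
        if len(idx) == 0:
            break
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        runs = [r for r in np.split(idx, splits) if len(r) >= min_bout]
        if not runs:
            break
        lens = np.array([len(r) for r in runs], dtype=float)
        length = max(min_bout, int(round(length_fn())))
        length = min(length, target - placed)
        if target - placed - length < min_bout:
            length = target - placed   # final bout absorbs the remainder
        if length < min_bout:
            break
        run = runs[int(rng.choice(len(runs), p=lens / lens.sum()))]
        if len(run) <= length:
            members = run
        else:
            s = int(rng.integers(0, len(run) - length + 1))
            members = run[s:s + length]
        free[max(0, members[0] - guard):min(n, members[-1] + 1 + guard)] = False
        bouts.append(np.asarray(members, dtype=int))
        placed += len(members)
    return bouts


def simulate_behavior(params: BehaviorParams) -> BehaviorTrace:
    """Generate the per-minute ground-truth state/tuck trace.

    Daily daylight flight and tuck fractions are Beta draws (moment-matched to
    the configured mean/SD); flight is forced to zero inside molt windows.
    Tuck bouts are lognormal (median ``tuck_bout_median_min``); each daylight
    bout involves both legs with probability ``p_both_tuck_day``, otherwise one
    leg at random, while night bouts are mostly both-leg.  Burrow visits occur
    at night within the attendance window.
    """
    if params.flight_frac_mean + params.tuck_frac_mean > 1:
        raise ValueError("infeasible activity budget: flight + tuck fractions exceed 1")
    rng = np.random.default_rng([params.seed, 0x7ac5])
    track = simulate_track(params)
    start = pd.Timestamp(params.start).normalize()
    end = pd.Timestamp(params.end).normalize() + pd.Timedelta(days=1)
    minutes = pd.date_range(start, end, freq="min", inclusive="left")
    n_days = len(track)
    elev = solar.elevation_for_times(minutes, positions=track)
    state = np.full(len(minutes), SURFACE, dtype=np.int8)
    tuck = np.full(len(minutes), NO_TUCK, dtype=np.int8)

    molt_day = np.zeros(n_days, dtype=bool)
    dates = pd.DatetimeIndex(track["date"])
    for m0, m1 in params.molt_ranges():
        molt_day |= (dates >= m0) & (dates <= m1)

    tk_a, tk_b = _beta_params(params.tuck_frac_mean, params.tuck_frac_sd)
    nt_a, nt_b = _beta_params(params.night_tuck_frac, params.night_tuck_sd)
    bw_m, bw_d = params.burrow_window_start
    lognorm_mu = np.log(params.tuck_bout_median_min)

    def tuck_len():
        return float(np.exp(lognorm_mu + params.tuck_bout_sigma * rng.standard_normal()))

    def flight_len():
        return float(rng.exponential(params.flight_bout_mean_min)) + 3.0

    for d in range(n_days):
        sl = slice(d * 1440, (d + 1) * 1440)
        e = elev[sl]
        st = state[sl]
        tk = tuck[sl]
        daylight = e > DAYLIGHT_DEG
        n_day = int(daylight.sum())
        night = ~daylight

        # burrow visit (night only, attendance window)
        date = dates[d]
        in_window = (date.month, date.day) >= (bw_m, bw_d) and date.month <= 7
        if in_window and rng.random() < params.burrow_visit_prob and night.sum() > 30:
            length = int(rng.uniform(*params.burrow_bout_min))
            night_idx = np.flatnonzero(night)
            s0 = int(night_idx[rng.integers(len(night_idx))])
            j = s0
            while j < 1440 and night[j] and (j - s0) < length:
                st[j] = BURROW
                j += 1

        free_day = daylight & (st == SURFACE)

        if not molt_day[d] and n_day > 0:
            # truncated-normal daily flight fraction (rejection sampling)
            f = -1.0
            while not 0.0 <= f <= 1.0:
                f = params.flight_frac_mean + params.flight_frac_sd * rng.standard_normal()
            for bout in _place_bouts(rng, free_day, int(round(f * n_day)), flight_len,
                                     min_bout=5):
                st[bout] = FLIGHT
            free_day = daylight & (st == SURFACE)

        if n_day > 0:
            t_frac = rng.beta(tk_a, tk_b)
            tuck_target = int(round(t_frac * n_day))
            # a day spent mostly tucked is continuous rafting, not many short
            # bouts: long spells also pack into the available surface time
            day_len = tuck_len if tuck_target <= 0.5 * free_day.sum() \
                else (lambda: tuck_target)
            bouts = _place_bouts(rng, free_day, tuck_target, day_len,
                                 min_bout=params.tuck_bout_min_min, guard=10)
            remaining = tuck_target - sum(len(b) for b in bouts)
            if remaining >= params.tuck_bout_min_min:
                # heavy-tuck days exhaust guarded space; top up with minimal spacing
                bouts += _place_bouts(rng, free_day, remaining, tuck_len,
                                      min_bout=params.tuck_bout_min_min, guard=2)
            for bout in bouts:
                if len(bout) == 0:
                    continue
                if rng.random() < params.p_both_tuck_day:
                    tk[bout] = TUCK_BOTH
                else:
                    tk[bout] = TUCK_LEFT if rng.random() < 0.5 else TUCK_RIGHT

        # dives fill time left over after tucking: scattering random single
        # minutes first would fragment the surface runs tuck bouts need
        if n_day > 0 and params.dive_frac > 0:
            n_dive = int(round(params.dive_frac * n_day * rng.uniform(0.5, 1.5)))
            free_idx = np.flatnonzero(free_day)
            if len(free_idx) and n_dive:
                pick = np.sort(rng.choice(free_idx, size=min(n_dive, len(free_idx)),
                                          replace=False))
                # individual dives last under ~2 min: break up chance runs
                keep = np.ones(len(pick), dtype=bool)
                run = 1
                for i in range(1, len(pick)):
                    run = run + 1 if (pick[i] == pick[i - 1] + 1 and keep[i - 1]) else 1
                    if run > 2:
                        keep[i] = False
                        run = 0
                pick = pick[keep]
                st[pick] = DIVE
                free_day[pick] = False

        deep_night = (e < params.night_tuck_max_elevation)
        free_night = deep_night & (st == SURFACE)
        n_night = int(deep_night.sum())
        if n_night > 0:
            nt = rng.beta(nt_a, nt_b)
            for bout in _place_bouts(rng, free_night, int(round(nt * n_night)), tuck_len,
                                     min_bout=params.tuck_bout_min_min, guard=10):
                if len(bout) == 0:
                    continue
                if rng.random() < params.p_both_tuck_night:
                    tk[bout] = TUCK_BOTH
                else:
                    tk[bout] = TUCK_LEFT if rng.random() < 0.5 else TUCK_RIGHT

    # brief preening/posture moments with both legs out of the water: the
    # fine-grained noise floor that keeps flightless-period dry time near,
    # not at, zero (counted in the loggers' 3-s samples, 20 per minute)
    blip = rng.poisson(20.0 * params.preen_dry_frac, size=len(minutes)).astype(np.int8)
    blip = np.minimum(blip, 20)
    blip[state != SURFACE] = 0
    return BehaviorTrace(minutes=minutes, state=state, tuck=tuck, elevation=elev,
                         positions=track, params=params, dry_blip=blip)


def _leg_obscured(trace: BehaviorTrace, leg: str) -> np.ndarray:
    code = TUCK_LEFT if leg == "left" else TUCK_RIGHT
    return (trace.tuck == code) | (trace.tuck == TUCK_BOTH)


def render_light(trace: BehaviorTrace, fix_interval: int = 5, leg: str = "left") -> LightSeries:
    """Render the per-fix maximum light series one logger would record.

    Per-minute ambient light is a logistic function of solar elevation scaled
    to 0-64, attenuated by a daily cloud factor and small per-minute noise;
    minutes with this logger's leg tucked are darkened by a per-bout opacity
    (fully dark for most bouts, partially translucent otherwise); burrow
    minutes are dark.  Submersion does not reduce the fix maximum.  The saved
    value per fix is the maximum over the interval, quantised to 0-64.
    """
    p = trace.params.render
    rng = np.random.default_rng([trace.params.seed, 0x11647, 0 if leg == "left" else 1,
                                 fix_interval])
    ambient = 64.0 / (1.0 + np.exp(-(trace.elevation - p.light_midpoint_deg) / p.light_scale_deg))
    cloud = rng.uniform(p.cloud_range[0], p.cloud_range[1], size=len(trace.positions))
    factor = cloud[trace.day_index]
    obscured = _leg_obscured(trace, leg)
    # per-bout opacity over maximal obscured runs
    attn = np.ones(len(ambient))
    d = np.diff(obscured.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if obscured[0]:
        starts = np.concatenate([[0], starts])
    if obscured[-1]:
        ends = np.concatenate([ends, [len(obscured)]])
    for s0, e0 in zip(starts, ends):
        # a both-leg tuck is a deep-rest posture: always fully obscured;
        # loose (translucent) tucks only occur with a single leg
        if trace.tuck[s0] == TUCK_BOTH or rng.random() < p.tuck_opacity_prob:
            attn[s0:e0] = 0.0
        else:
            attn[s0:e0] = rng.uniform(*p.translucent_range)
    light_min = ambient * factor * attn
    light_min[trace.state == BURROW] = 0.0
    # signal-dependent sensor noise: a dark sensor reads a solid 0
    noise = rng.normal(0.0, p.noise_sd, size=len(light_min)) * np.sqrt(light_min / 8.0)
    light_min = np.clip(np.round(light_min + noise), 0, 64)
    per_fix = light_min.reshape(-1, fix_interval).max(axis=1).astype(int)
    times = trace.minutes[::fix_interval]
    data = pd.DataFrame({"light": per_fix}, index=times)
    return LightSeries(logger_id=f"sim{trace.params.seed}-{leg}", leg=leg,
                       data=data, fix_interval=fix_interval)


def render_immersion(trace: BehaviorTrace, leg: str = "left", fix_interval: int = 10) -> ImmersionSeries:
    """Render the 3-s wet-count series one logger would record.

    A minute is wet when the bird is on the water or diving and this leg is
    not tucked; flight, burrow and tucked-leg minutes are dry.  Wet 3-s
    samples aggregate to counts of 0-200 per 10-min bin (the trace has 1-min
    resolution, so counts come in steps of 20).
    """
    wet_min = ((trace.state == SURFACE) | (trace.state == DIVE)) & ~_leg_obscured(trace, leg)
    samples = np.where(wet_min, 20, 0)
    if trace.dry_blip is not None:
        samples = np.where(wet_min, samples - trace.dry_blip, samples)
    counts = samples.reshape(-1, fix_interval).sum(axis=1)
    times = trace.minutes[::fix_interval]
    data = pd.DataFrame({"wet_count": counts.astype(int)}, index=times)
    return ImmersionSeries(logger_id=f"sim{trace.params.seed}-{leg}", leg=leg,
                           data=data, fix_interval=fix_interval, scale_max=20 * fix_interval)


def ground_truth(trace: BehaviorTrace) -> dict:
    """Exact per-stage scoring labels for the simulated bird."""
    di = trace.day_index
    daylight = trace.elevation > DAYLIGHT_DEG
    n_days = len(trace.positions)
    day_min = np.bincount(di, weights=daylight, minlength=n_days)
    fl_min = np.bincount(di, weights=daylight & (trace.state == FLIGHT), minlength=n_days)
    tk_min = np.bincount(di, weights=daylight & (trace.tuck != NO_TUCK), minlength=n_days)
    with np.errstate(invalid="ignore", divide="ignore"):
        daily = pd.DataFrame({
            "date": pd.DatetimeIndex(trace.positions["date"]),
            "true_flight_frac": np.where(day_min > 0, fl_min / np.maximum(day_min, 1), np.nan),
            "true_tuck_frac": np.where(day_min > 0, tk_min / np.maximum(day_min, 1), np.nan),
            "daylight_minutes": day_min.astype(int),
        })
    return {
        "molt_windows": trace.params.molt_ranges(),
        "daily": daily,
        "minute_states": trace.state.copy(),
        "minute_tuck": trace.tuck.copy(),
    }
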