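"""Threshold light-level geolocation.

Twilights are detected where the raw light series crosses a fixed level
(default 1 on the 0-64 logger scale), cleaned with a moving-window editor,
and converted to one position per daylight period: longitude from the
midpoint of sunrise and sunset (with the equation of time), latitude by
inverting the sunrise hour-angle equation for a calibrated solar zenith.
Zenith calibration follows the Hills-Ekstrom idea: the zenith that minimises
the variance of latitude about its low-frequency trend (plus a penalty for
latitudes that admit no solution) over repeated latitude runs.

Equinox latitudes are smoothed with LOESS over two-month windows and linearly
interpolated over the core equinox weeks; residency is segmented on the daily
colony-distance series by Lavielle's penalised-contrast changepoint method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import solar
from .geo_io import LightSeries

logger = logging.getLogger(__name__)

_DEG = np.pi / 180.0
EARTH_RADIUS_KM = 6371.0

# LOESS window (month, day) bounds, outer smoothing and inner interpolation
AUTUMN_OUTER = ((8, 22), (10, 23))
SPRING_OUTER = ((2, 19), (4, 22))
AUTUMN_INNER = ((9, 1), (10, 13))
SPRING_INNER = ((3, 1), (4, 12))


@dataclass
class TwilightEvent:
    time: pd.Timestamp
    kind: str                     # "rise" | "set"
    status: str = "kept"          # "kept" | "adjusted" | "deleted"
    original_time: pd.Timestamp | None = None

    def __post_init__(self):
        if self.kind not in ("rise", "set"):
            raise ValueError(f"kind must be rise|set, got {self.kind}")
        if self.original_time is None:
            self.original_time = self.time


@dataclass
class ZenithCalibration:
    zenith: float
    search_range: tuple[float, float]
    objective: pd.Series  # candidate zenith -> objective value


@dataclass
class ResidencySegment:
    start: pd.Timestamp
    end: pd.Timestamp
    mean_lon: float
    mean_lat: float
    mean_colony_distance_km: float

    @property
    def duration_days(self) -> int:
        return int((self.end - self.start).days) + 1


class CalibrationError(RuntimeError):
    pass


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on a spherical Earth (R = 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) * _DEG for x in (lat1, lon1, lat2, lon2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


# ---------------------------------------------------------------------------
# twilight detection and editing
# ---------------------------------------------------------------------------

def detect_twilights(light: LightSeries, light_threshold: float = 1.0,
                     min_dark_hours: float = 4.0, min_light_hours: float = 2.0) -> list[TwilightEvent]:
    """Find day/night threshold crossings of the raw light series.

    Only crossings bounding a *sustained* dark period qualify as twilights: a
    below-threshold run must last at least ``min_dark_hours`` to count as
    night (shorter dark spells are shading artifacts, e.g. a tucked leg), and
    nights separated by less than ``min_light_hours`` of light are merged
    (sensor blips must not split a night).  The crossing time is linearly
    interpolated between the two fixes bracketing the threshold; sunsets start
    a night, sunrises end one.
    """
    t = light.data.index.asi8 / 1e9  # unix seconds
    v = light.data["light"].to_numpy(dtype=float)
    if len(v) < 2:
        logger.warning("light series too short for twilight detection")
        return []
    dark = v < light_threshold
    if dark.all() or not dark.any():
        logger.warning("no twilight crossings found (constant light?)")
        return []
    d = np.diff(dark.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1          # first dark fix of a run
    ends = np.flatnonzero(d == -1) + 1           # first light fix after a run
    if dark[0]:
        starts = np.concatenate([[0], starts])
    if dark[-1]:
        ends = np.concatenate([ends, [len(v)]])
    runs = [(s, e) for s, e in zip(starts, ends) if t[e - 1] - t[s] >= min_dark_hours * 3600.0]
    # merge nights separated by too little light
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and t[s] - t[merged[-1][1] - 1] < min_light_hours * 3600.0:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    def _cross(i: int, j: int) -> pd.Timestamp:
        frac = (light_threshold - v[i]) / (v[j] - v[i])
        return pd.Timestamp(t[i] + frac * (t[j] - t[i]), unit="s")

    max_gap = 2 * light.fix_interval * 60.0
    events: list[TwilightEvent] = []
    for s, e in merged:
        if s > 0 and t[s] - t[s - 1] <= max_gap and v[s - 1] > v[s]:
            events.append(TwilightEvent(_cross(s - 1, s), "set"))
        if e < len(v) and t[e] - t[e - 1] <= max_gap and v[e] > v[e - 1]:
            events.append(TwilightEvent(_cross(e - 1, e), "rise"))
    events.sort(key=lambda ev: ev.time)
    if not events:
        logger.warning("no twilight crossings found (constant light?)")
    return events


def _minutes_of_day(ts: pd.Timestamp) -> float:
    return (ts - ts.normalize()).total_seconds() / 60.0


def _circular_median_diff(value: float, others: np.ndarray) -> tuple[float, np.ndarray]:
    """Median of times-of-day (minutes) near ``value`` with day wraparound.

    Returns (median, deviations of others about that median).
    """
    # unwrap others onto the branch closest to value
    o = others.copy()
    o += 1440.0 * np.round((value - o) / 1440.0)
    med = float(np.median(o))
    return med, o - med


def edit_twilights(events: list[TwilightEvent], window: int = 4,
                   outlier_mins: float = 45.0, stationary_mins: float = 15.0) -> list[TwilightEvent]:
    """Moving-window editor for improbable twilights.

    An event whose time-of-day deviates more than ``outlier_mins`` from the
    median of same-kind events in the surrounding ``window`` days is adjusted
    to that median when the neighbours themselves agree within
    ``stationary_mins`` (a stationary bird, so the outlier is an artifact,
    e.g. prolonged leg tucking); otherwise it is deleted (possibly genuine
    movement, but unusable).  Events are returned in the same order; deleted
    events keep their slot with ``status='deleted'``.
    """
    if not events:
        return []
    times = np.array([e.time.value for e in events], dtype=np.int64)
    if np.any(np.diff(times) < 0):
        raise ValueError("events must be time-sorted")
    kinds = np.array([e.kind for e in events])
    n_per_kind = min((kinds == "rise").sum(), (kinds == "set").sum())
    if n_per_kind < window:
        logger.warning("fewer events than editing window; returned unchanged")
        return events
    mods = np.array([_minutes_of_day(e.time) for e in events])
    days = np.array([e.time.normalize().value for e in events], dtype=np.int64)
    out: list[TwilightEvent] = []
    half = pd.Timedelta(days=window).value
    for i, ev in enumerate(events):
        same = (kinds == ev.kind) & (np.abs(days - days[i]) <= half)
        same[i] = False
        neigh = mods[same]
        if len(neigh) < 2:
            out.append(ev)
            continue
        med, devs = _circular_median_diff(mods[i], neigh)
        dev_i = mods[i] - med
        dev_i -= 1440.0 * np.round(dev_i / 1440.0)
        if abs(dev_i) <= outlier_mins:
            out.append(ev)
            continue
        if np.max(np.abs(devs)) <= stationary_mins:
            new_time = ev.time.normalize() + pd.Timedelta(minutes=float(med) % 1440.0)
            # keep the adjusted event on the same side of midnight as the original
            if new_time - ev.time > pd.Timedelta(hours=12):
                new_time -= pd.Timedelta(days=1)
            elif ev.time - new_time > pd.Timedelta(hours=12):
                new_time += pd.Timedelta(days=1)
            out.append(TwilightEvent(new_time, ev.kind, status="adjusted",
                                     original_time=ev.time))
        else:
            out.append(TwilightEvent(ev.time, ev.kind, status="deleted",
                                     original_time=ev.time))
    return out


# ---------------------------------------------------------------------------
# positions
# ---------------------------------------------------------------------------

def _latitude_from_daylength(decl_deg, half_ha_deg, zenith) -> np.ndarray:
    """Invert sin(alt0) = sin(lat)sin(decl) + cos(lat)cos(decl)cos(H) for latitude.

    Vectorised.  Returns NaN where no latitude satisfies the observed day
    length (equinox degeneracy or an impossible geometry for this zenith).
    When both roots lie in [-90, 90] (only near the equinox), the equatorward
    one is returned; such latitudes are later overwritten by the equinox
    smoother anyway.
    """
    a = np.sin(np.asarray(decl_deg, dtype=float) * _DEG)
    b = np.cos(np.asarray(decl_deg, dtype=float) * _DEG) * np.cos(np.asarray(half_ha_deg, dtype=float) * _DEG)
    c = np.cos(zenith * _DEG)
    r = np.hypot(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (r > 1e-12) & (np.abs(c) <= r)
        alpha = np.arcsin(np.clip(np.where(ok, c / np.where(r > 0, r, 1.0), 0.0), -1, 1)) / _DEG
        theta = np.arctan2(b, a) / _DEG
        r1 = (alpha - theta + 180.0) % 360.0 - 180.0
        r2 = (180.0 - alpha - theta + 180.0) % 360.0 - 180.0
        v1 = np.abs(r1) <= 90.0
        v2 = np.abs(r2) <= 90.0
        pick2 = v2 & (~v1 | (np.abs(r2) < np.abs(r1)))
        lat = np.where(pick2, r2, r1)
        lat = np.where(ok & (v1 | v2), lat, np.nan)
    return lat


def position_from_twilight_pair(rise: TwilightEvent, sett: TwilightEvent, zenith: float) -> dict:
    """One position fix from a sunrise/sunset pair.

    Longitude comes from the midpoint of the pair against true solar noon
    (equation of time included, 15 deg/h); latitude from day length through
    the hour-angle equation at the given zenith.  Degenerate day lengths give
    ``lat=NaN`` with ``lat_quality='undefined'``; longitude is always defined.
    """
    if sett.time <= rise.time:
        raise ValueError("rise must precede set")
    df = _positions_from_pairs(np.array([rise.time.value]), np.array([sett.time.value]), zenith)
    return df.iloc[0].to_dict()


def _positions_from_pairs(rise_ns: np.ndarray, set_ns: np.ndarray, zenith: float) -> pd.DataFrame:
    mid = pd.DatetimeIndex((rise_ns + (set_ns - rise_ns) // 2).astype("datetime64[ns]"))
    decl, eqtime = solar.sun_declination_eqtime(mid)
    mod = (mid.asi8 - mid.normalize().asi8) / 60e9  # minutes of day
    lon = (720.0 - mod - eqtime) / 4.0
    lon = (lon + 180.0) % 360.0 - 180.0
    half_ha = (set_ns - rise_ns) / 60e9 / 8.0  # degrees
    lat = _latitude_from_daylength(decl, half_ha, zenith)
    return pd.DataFrame({
        "date": mid.normalize(),
        "lon": lon,
        "lat": lat,
        "lat_quality": np.where(np.isnan(lat), "undefined", "raw"),
    })


def pair_twilights(events: list[TwilightEvent]) -> list[tuple[TwilightEvent, TwilightEvent]]:
    """Rise/set pairs sharing one daylight period (set follows rise within 24 h)."""
    live = [e for e in events if e.status != "deleted"]
    pairs = []
    for a, b in zip(live[:-1], live[1:]):
        if (a.kind == "rise" and b.kind == "set"
                and pd.Timedelta(0) < (b.time - a.time) < pd.Timedelta(hours=24)):
            pairs.append((a, b))
    return pairs


def positions_from_twilights(events: list[TwilightEvent], zenith: float) -> pd.DataFrame:
    """Daily position fixes (date, lon, lat, lat_quality) from edited twilights."""
    pairs = pair_twilights(events)
    if not pairs:
        return pd.DataFrame(columns=["date", "lon", "lat", "lat_quality"])
    rise_ns = np.array([r.time.value for r, _ in pairs], dtype=np.int64)
    set_ns = np.array([s.time.value for _, s in pairs], dtype=np.int64)
    df = _positions_from_pairs(rise_ns, set_ns, zenith)
    return df.groupby("date", as_index=False).first()  # one fix per calendar day


# ---------------------------------------------------------------------------
# zenith calibration (Hills-Ekstrom)
# ---------------------------------------------------------------------------

def calibrate_zenith(events: list[TwilightEvent],
                     search: np.ndarray | None = None,
                     window_days: int = 21,
                     undefined_penalty: float = 10.0,
                     max_objective: float = 400.0) -> ZenithCalibration:
    """Most likely solar zenith from repeated latitude runs (Hills-Ekstrom).

    A wrong zenith turns the seasonal declination cycle into spurious
    latitude drift, largest near the equinoxes.  For each candidate zenith
    the full latitude series is computed; the objective is the median, over
    centred ``window_days`` rolling windows, of the within-window latitude
    variance — variance about a locally-constant trend, so genuine migration
    (slow, between-window) barely contributes while wrong-zenith drift
    (fast, within-window) does.  Windows are evaluated on the days whose
    latitude is defined for *every* candidate, so candidates cannot win by
    censoring diverging equinox latitudes into undefined; a small penalty
    (deg^2 per unit fraction undefined) breaks residual flats.  The candidate
    minimising the objective wins; ties go to the smaller zenith.
    """
    if search is None:
        search = np.arange(90.0, 100.0 + 1e-9, 0.25)
    pairs = pair_twilights(events)
    if len(pairs) < 60:
        raise CalibrationError(f"need >= 60 twilight pairs, got {len(pairs)}")
    rise_ns = np.array([r.time.value for r, _ in pairs], dtype=np.int64)
    set_ns = np.array([s.time.value for _, s in pairs], dtype=np.int64)
    lat_by_z = {}
    frac_undef = {}
    for z in search:
        fixes = _positions_from_pairs(rise_ns, set_ns, z)
        s = pd.Series(fixes["lat"].to_numpy(), index=pd.DatetimeIndex(fixes["date"]))
        lat_by_z[float(z)] = s
        frac_undef[float(z)] = float(s.isna().mean())
    if min(frac_undef.values()) > 0.5:
        raise CalibrationError("all candidate zeniths yield >50% undefined latitudes")
    common = None
    for s in lat_by_z.values():
        ok = s.notna()
        common = ok if common is None else (common & ok)
    objective = {}
    best = None
    for z, s in lat_by_z.items():
        v = s[common.reindex(s.index, fill_value=False)]
        if len(v) >= window_days:
            wv = v.rolling(window_days, center=True, min_periods=max(5, window_days // 2)).var()
            obj = float(np.nanmedian(wv.to_numpy()))
        else:
            obj = np.inf
        obj = obj + undefined_penalty * frac_undef[z]
        objective[z] = obj
        if np.isfinite(obj) and frac_undef[z] <= 0.5 and (best is None or obj < best[1]):
            best = (z, obj)
    if best is None:
        raise CalibrationError("zenith calibration objective undefined for every candidate")
    if best[1] > max_objective:
        # even the best candidate leaves tens of degrees of within-window
        # latitude scatter: the twilight series carries no zenith signal
        raise CalibrationError(
            f"no candidate zenith explains the twilight series (objective {best[1]:.0f} deg^2)")
    trace = pd.Series(objective, name="objective")
    return ZenithCalibration(zenith=best[0], search_range=(float(search[0]), float(search[-1])),
                             objective=trace)


# ---------------------------------------------------------------------------
# equinox smoothing
# ---------------------------------------------------------------------------

def _window_mask(dates: pd.DatetimeIndex, bounds: tuple[tuple[int, int], tuple[int, int]]) -> np.ndarray:
    (m0, d0), (m1, d1) = bounds
    key = dates.month * 100 + dates.day
    return (key >= m0 * 100 + d0) & (key <= m1 * 100 + d1)


def smooth_latitudes(fixes: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Equinox smoothing of latitudes.

    Within the two-month windows around each equinox (Aug 22 - Oct 23 and
    Feb 19 - Apr 22) latitudes are replaced by a LOESS (local linear, span
    ``span``) fit over date; within the core windows (Sep 1 - Oct 13 and
    Mar 1 - Apr 12) they are then replaced by linear interpolation between the
    smoothed values at the core-window edges.  Longitudes are untouched.
    """
    out = fixes.copy().reset_index(drop=True)
    dates = pd.DatetimeIndex(out["date"])
    day_num = dates.asi8 / 86400e9
    for outer, inner in ((AUTUMN_OUTER, AUTUMN_INNER), (SPRING_OUTER, SPRING_INNER)):
        mask = _window_mask(dates, outer)
        # process each contiguous yearly occurrence of the window separately
        for year in np.unique(dates[mask].year):
            wsel = mask & np.isin(dates.year, [year, year])  # windows never span Jan 1
            wsel = mask & (dates.year == year)
            ok = wsel & out["lat"].notna().to_numpy()
            if ok.sum() < 5:
                logger.warning("equinox window %s %s: too few defined latitudes, skipped", year, outer)
                continue
            sm = lowess(out.loc[ok, "lat"].to_numpy(), day_num[ok],
                        frac=min(1.0, max(span, 5 / ok.sum())), return_sorted=False)
            out.loc[ok, "lat"] = sm
            out.loc[ok, "lat_quality"] = "loess_smoothed"
            isel = _window_mask(dates, inner) & (dates.year == year)
            core = isel & out["lat"].notna().to_numpy()
            edges = ok & ~isel
            lo = edges & (day_num < day_num[isel].min() if isel.any() else False)
            hi = edges & (day_num > day_num[isel].max() if isel.any() else False)
            if not isel.any() or not lo.any() or not hi.any():
                logger.warning("equinox core window %s %s: missing edge values, interpolation skipped",
                               year, inner)
                continue
            x0, y0 = day_num[lo][-1], out.loc[np.flatnonzero(lo)[-1], "lat"]
            x1, y1 = day_num[hi][0], out.loc[np.flatnonzero(hi)[0], "lat"]
            xi = day_num[core]
            out.loc[core, "lat"] = y0 + (y1 - y0) * (xi - x0) / (x1 - x0)
            out.loc[core, "lat_quality"] = "interpolated"
    return out


# ---------------------------------------------------------------------------
# residency segmentation (Lavielle penalised contrast)
# ---------------------------------------------------------------------------

def _optimal_segmentations(y: np.ndarray, kmax: int, min_len: int) -> tuple[np.ndarray, list[list[int]]]:
    """Dynamic-programming least-squares segmentation.

    Returns (J, breaks) where J[k-1] is the minimal within-segment sum of
    squares using k segments and breaks[k-1] the corresponding changepoint
    list (end indices, exclusive, excluding n).
    """
    n = len(y)
    c1 = np.cumsum(np.concatenate([[0.0], y]))
    c2 = np.cumsum(np.concatenate([[0.0], y * y]))

    def sse(i, j):  # cost of segment y[i:j]
        s = c1[j] - c1[i]
        return (c2[j] - c2[i]) - s * s / (j - i)

    cost = np.full((n + 1, n + 1), np.inf)
    for i in range(n):
        for j in range(i + min_len, n + 1):
            cost[i, j] = sse(i, j)
    J = np.full(kmax, np.inf)
    D = np.full((kmax, n + 1), np.inf)
    argmin = np.zeros((kmax, n + 1), dtype=int)
    D[0] = cost[0]
    for k in range(1, kmax):
        for j in range((k + 1) * min_len, n + 1):
            cand = D[k - 1, : j - min_len + 1] + cost[: j - min_len + 1, j]
            i = int(np.argmin(cand))
            D[k, j] = cand[i]
            argmin[k, j] = i
    breaks: list[list[int]] = []
    for k in range(kmax):
        J[k] = D[k, n]
        bl: list[int] = []
        j = n
        for kk in range(k, 0, -1):
            i = argmin[kk, j]
            bl.append(i)
            j = i
        breaks.append(sorted(bl))
    return J, breaks


def _lavielle_choose_k(J: np.ndarray, d2_threshold: float = 0.75,
                       structure_threshold: float = 0.5) -> int:
    """Lavielle's elbow rule on the normalised contrast curve.

    One segment is returned when the first changepoint explains too little of
    the contrast (pure noise: the optimal-SSE curve declines only by
    min-length overfitting); otherwise the largest K whose normalised
    second difference exceeds the threshold wins, defaulting to 2.
    """
    kmax = len(J)
    if kmax <= 1 or J[0] <= 1e-12:
        return 1
    if J[1] / J[0] > structure_threshold:
        return 1
    if kmax == 2:
        return 2
    denom = J[0] - J.min()
    if denom <= 1e-12:
        return 1
    jn = (J - J.min()) / denom * (kmax - 1) + 1  # Jn[0]=kmax .. min=1
    d2 = jn[:-2] - 2 * jn[1:-1] + jn[2:]  # second difference at k=2..kmax-1
    ks = np.arange(2, kmax)
    good = ks[d2 >= d2_threshold]
    return int(good.max()) if len(good) else 2


def segment_residencies(fixes: pd.DataFrame, colony: tuple[float, float],
                        min_segment_days: int = 7, max_segments: int = 10,
                        elbow_threshold: float = 0.75) -> list[ResidencySegment]:
    """Changepoint segmentation of the daily colony-distance series.

    Uses penalised least-squares (Lavielle's contrast) with a minimum segment
    length; the number of segments comes from the elbow of the normalised
    contrast curve.  Each segment reports its mean position and mean
    great-circle distance to the colony.
    """
    df = fixes.dropna(subset=["lat", "lon"]).sort_values("date").reset_index(drop=True)
    if len(df) < 30:
        raise ValueError(f"need >= 30 daily fixes for segmentation, got {len(df)}")
    dist = haversine_km(df["lat"].to_numpy(), df["lon"].to_numpy(), colony[0], colony[1])
    n = len(dist)
    kmax = max(1, min(max_segments, n // min_segment_days))
    if n < 2 * min_segment_days:
        kmax = 1
    J, breaks = _optimal_segmentations(dist.astype(float), kmax, min_segment_days)
    k = _lavielle_choose_k(J[:kmax], elbow_threshold)
    bounds = [0] + breaks[k - 1] + [n]
    segments = []
    dates = pd.DatetimeIndex(df["date"])
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        segments.append(ResidencySegment(
            start=dates[i0], end=dates[i1 - 1],
            mean_lon=float(df["lon"].iloc[i0:i1].mean()),
            mean_lat=float(df["lat"].iloc[i0:i1].mean()),
            mean_colony_distance_km=float(dist[i0:i1].mean()),
        ))
    return segments


def migration_metrics(segments: list[ResidencySegment]) -> dict:
    """Distance and duration of the most distant residency segment."""
    if not segments:
        return {"max_distance_km": np.nan, "duration_days": 0}
    far = max(segments, key=lambda s: s.mean_colony_distance_km)
    return {"max_distance_km": far.mean_colony_distance_km,
            "duration_days": far.duration_days}
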