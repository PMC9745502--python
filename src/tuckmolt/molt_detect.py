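"""Flightless-molt detection from corrected immersion data.

The corrected proportion of daylight time spent dry per day is taken as the
proportion of time in flight (``prop_flight``); its 5-day centred rolling
mean (``prop_flight5``) smooths residual tucking noise.  A flightless molt is
a run of at least 30 consecutive days during which ``prop_flight5`` stays
below a threshold found by incrementing from 0 in 0.0002 steps until such a
run first appears, capped at 1% (longer voluntarily-resident spells of merely
reduced flight must not be mistaken for molt).  The scan is repeated once
with the first window excluded, to allow for a second flightless molt.

Only day sections with solar elevation above -3 deg enter the daily
proportion: nocturnal dry spells are dominated by both-leg tucking and burrow
visits, which no light-based correction can see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo_io import ImmersionSeries

logger = logging.getLogger(__name__)

DAYLIGHT_ELEVATION_DEG = -3.0
THRESHOLD_STEP = 0.0002
MIN_MOLT_DAYS = 30
THRESHOLD_CAP = 0.01
MAX_BRIDGEABLE_GAP = 2   # undefined-day gaps of >= 3 days break runs


@dataclass
class MoltWindow:
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    iteration: int
    threshold_used: float
    basis: str = "combined"        # left | right | single | combined

    @property
    def duration_days(self) -> int:
        return int((self.end_date - self.start_date).days) + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, self.end_date, freq="D")


def daily_flight_proportion(imm: ImmersionSeries, elevations: np.ndarray,
                            min_elevation: float = DAYLIGHT_ELEVATION_DEG) -> pd.DataFrame:
    """Per-day proportion of daylight time spent dry.

    ``elevations`` holds one solar elevation per immersion bin.  Bins with
    elevation above ``min_elevation`` are pooled per UTC calendar day;
    ``prop_flight`` is 1 minus the mean wet proportion over those bins.  Days
    without daylight bins are undefined (NaN).
    """
    elev = np.asarray(elevations, dtype=float)
    if len(elev) != len(imm):
        raise ValueError("elevations must align with immersion bins")
    if len(imm) == 0:
        return pd.DataFrame(columns=["date", "prop_flight", "n_daylight_fixes"])
    day_mask = elev > min_elevation
    frame = pd.DataFrame({
        "date": imm.times.normalize(),
        "wet": imm.wet_proportion,
        "day": day_mask,
    })
    frame = frame[frame["day"]]
    grouped = frame.groupby("date")["wet"].agg(["mean", "count"])
    all_days = pd.date_range(imm.times[0].normalize(), imm.times[-1].normalize(), freq="D")
    out = pd.DataFrame(index=all_days)
    out["prop_flight"] = 1.0 - grouped["mean"].reindex(all_days)
    out["n_daylight_fixes"] = grouped["count"].reindex(all_days).fillna(0).astype(int)
    out.index.name = "date"
    return out.reset_index()


def rolling_mean5(days: pd.DataFrame) -> pd.DataFrame:
    """5-day centred rolling mean of ``prop_flight`` (needs >= 3 defined days)."""
    out = days.copy().reset_index(drop=True)
    idx = pd.DatetimeIndex(out["date"])
    full = pd.date_range(idx.min(), idx.max(), freq="D")
    pf = pd.Series(out["prop_flight"].to_numpy(), index=idx).reindex(full)
    pf5 = pf.rolling(window=5, center=True, min_periods=3).mean()
    out["prop_flight5"] = pf5.reindex(idx).to_numpy()
    return out


def _run_spans(good: np.ndarray, neutral: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of good days, allowing interior neutral days, trimmed to good ends.

    ``good`` and ``neutral`` are disjoint boolean day masks over a contiguous
    daily index; everything else is blocking.  Returns (start, end) inclusive
    index pairs.
    """
    n = len(good)
    spans = []
    i = 0
    while i < n:
        if not (good[i] | neutral[i]):
            i += 1
            continue
        j = i
        while j + 1 < n and (good[j + 1] | neutral[j + 1]):
            j += 1
        # trim to first/last good day
        ks = np.flatnonzero(good[i:j + 1])
        if len(ks):
            spans.append((i + ks[0], i + ks[-1]))
        i = j + 1
    return spans


def find_molt_window(days: pd.DataFrame, step: float = THRESHOLD_STEP,
                     min_days: int = MIN_MOLT_DAYS, cap: float = THRESHOLD_CAP,
                     excluded: list[tuple] | None = None,
                     basis: str = "combined", iteration: int = 1) -> MoltWindow | None:
    """Incrementing-threshold scan for one flightless window.

    Thresholds step, 2*step, ... up to ``cap`` are tried in order; the first
    (smallest) threshold at which some run of at least ``min_days``
    consecutive days has every defined day's ``prop_flight5`` strictly below
    the threshold terminates the scan.  The longest qualifying run at that
    threshold (earliest on ties) is the *core* of the window; the reported
    window is that core extended over the surrounding consecutive days whose
    ``prop_flight5`` stays below ``cap`` — the flightless period is the
    continuous spell with less than 1% of daylight in flight, anchored on a
    persistently low core.  Runs may not bridge an excluded date range nor a
    gap of three or more consecutive undefined days, and must start and end
    on defined days; length counts calendar days inclusive.
    """
    df = days.dropna(subset=["date"]).sort_values("date").reset_index(drop=True)
    if len(df) < min_days:
        logger.warning("only %d days supplied (< %d); no molt window possible", len(df), min_days)
        return None
    idx = pd.DatetimeIndex(df["date"]).normalize()
    full = pd.date_range(idx.min(), idx.max(), freq="D")
    pf5 = pd.Series(df["prop_flight5"].to_numpy(), index=idx).reindex(full).to_numpy()
    blocked = np.zeros(len(full), dtype=bool)
    for r0, r1 in excluded or []:
        blocked |= (full >= pd.Timestamp(r0).normalize()) & (full <= pd.Timestamp(r1).normalize())
    defined = np.isfinite(pf5) & ~blocked
    # undefined gaps longer than MAX_BRIDGEABLE_GAP block runs
    undef = ~np.isfinite(pf5) & ~blocked
    gap_block = np.zeros(len(full), dtype=bool)
    i = 0
    while i < len(full):
        if undef[i]:
            j = i
            while j + 1 < len(full) and undef[j + 1]:
                j += 1
            if j - i + 1 > MAX_BRIDGEABLE_GAP:
                gap_block[i:j + 1] = True
            i = j + 1
        else:
            i += 1
    n_steps = int(np.floor(cap / step + 1e-9))
    for k in range(1, n_steps + 1):
        thr = k * step
        good = defined & (pf5 < thr)
        neutral = undef & ~gap_block
        spans = [s for s in _run_spans(good, neutral)
                 # every defined day inside must be good (no bad day bridged)
                 if not np.any(defined[s[0]:s[1] + 1] & (pf5[s[0]:s[1] + 1] >= thr))
                 and (s[1] - s[0] + 1) >= min_days]
        if spans:
            best = max(spans, key=lambda s: (s[1] - s[0], -s[0]))
            # extend the core over the surrounding sub-cap spell
            good_cap = defined & (pf5 < cap)
            for c0, c1 in _run_spans(good_cap, neutral):
                if c0 <= best[0] and c1 >= best[1]:
                    best = (c0, c1)
                    break
            return MoltWindow(start_date=full[best[0]], end_date=full[best[1]],
                              iteration=iteration, threshold_used=thr, basis=basis)
    return None


def detect_molts(days: pd.DataFrame, step: float = THRESHOLD_STEP,
                 min_days: int = MIN_MOLT_DAYS, cap: float = THRESHOLD_CAP,
                 basis: str = "combined") -> list[MoltWindow]:
    """Up to two flightless windows: full scan, then rescan excluding the first.

    Windows are returned chronologically, each labelled with the iteration at
    which it was found.
    """
    first = find_molt_window(days, step=step, min_days=min_days, cap=cap,
                             basis=basis, iteration=1)
    if first is None:
        return []
    second = find_molt_window(days, step=step, min_days=min_days, cap=cap,
                              excluded=[(first.start_date, first.end_date)],
                              basis=basis, iteration=2)
    windows = [first] + ([second] if second is not None else [])
    windows.sort(key=lambda w: w.start_date)
    return windows
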