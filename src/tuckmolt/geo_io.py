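"""Logger file I/O and the core time-series containers.

Canonical CSV dialect: ISO-8601 UTC timestamps in a ``timestamp`` column, one
row per fix.  Light files carry a ``light`` column (integer 0-64, the maximum
1-min reading saved per 5- or 10-min interval); immersion files carry a
``wet_count`` column (number of 3-s wet samples per 10-min bin, 0-200).
Vendor binary formats (.lig/.act) are out of scope; convert them to this
dialect first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIGHT_MAX = 64
WET_SCALE_MAX = 200
VALID_LEGS = ("left", "right", "unknown")


class SeriesValidationError(ValueError):
    pass


def _parse_timestamps(raw: pd.Series, path) -> pd.DatetimeIndex:
    try:
        ts = pd.to_datetime(raw, utc=True, format="ISO8601")
    except (ValueError, TypeError):
        # locate the offending row for the error message
        for i, v in enumerate(raw):
            try:
                pd.to_datetime(v, utc=True)
            except (ValueError, TypeError):
                raise SeriesValidationError(
                    f"{path}: malformed timestamp {v!r} at data row {i}") from None
        raise
    return pd.DatetimeIndex(ts).tz_convert("UTC").tz_localize(None)


def _infer_interval_minutes(index: pd.DatetimeIndex) -> int:
    if len(index) < 2:
        raise SeriesValidationError("cannot infer fix interval from <2 rows")
    steps = np.diff(index.asi8) / 60e9
    return int(np.median(steps))


@dataclass
class LightSeries:
    """Timestamped maximum-light fixes from one logger (UTC)."""

    logger_id: str
    leg: str
    data: pd.DataFrame              # DatetimeIndex (UTC, naive), column "light"
    fix_interval: int               # minutes, 5 or 10

    def __post_init__(self):
        if self.leg not in VALID_LEGS:
            raise SeriesValidationError(f"leg must be one of {VALID_LEGS}, got {self.leg!r}")
        if self.fix_interval not in (5, 10):
            raise SeriesValidationError(f"fix_interval must be 5 or 10, got {self.fix_interval}")
        v = self.data["light"].to_numpy()
        bad = (v < 0) | (v > LIGHT_MAX)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SeriesValidationError(
                f"light value {v[i]} outside [0, {LIGHT_MAX}] at row {i}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise SeriesValidationError(f"duplicate timestamp {dup} (corrupt export?)")
        if not self.data.index.is_monotonic_increasing:
            raise SeriesValidationError("timestamps not increasing after sort")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def light(self) -> np.ndarray:
        return self.data["light"].to_numpy()


@dataclass
class ImmersionSeries:
    """Timestamped wet-counts from one logger (UTC).

    ``wet_count`` may be fractional after correction/fusion; raw logger data
    are integers in [0, scale_max].
    """

    logger_id: str
    leg: str
    data: pd.DataFrame              # DatetimeIndex (UTC, naive), column "wet_count"
    fix_interval: int = 10          # minutes
    scale_max: int = WET_SCALE_MAX

    def __post_init__(self):
        if self.leg not in VALID_LEGS:
            raise SeriesValidationError(f"leg must be one of {VALID_LEGS}, got {self.leg!r}")
        v = self.data["wet_count"].to_numpy(dtype=float)
        bad = (v < 0) | (v > self.scale_max)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise SeriesValidationError(
                f"wet_count {v[i]} outside [0, {self.scale_max}] at row {i}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise SeriesValidationError(f"duplicate timestamp {dup} (corrupt export?)")
        if not self.data.index.is_monotonic_increasing:
            raise SeriesValidationError("timestamps not increasing after sort")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def wet_count(self) -> np.ndarray:
        return self.data["wet_count"].to_numpy(dtype=float)

    @property
    def wet_proportion(self) -> np.ndarray:
        return self.wet_count / self.scale_max


def _read_frame(path, value_col: str, dialect: dict | None) -> tuple[pd.DataFrame, dict]:
    dialect = dict(dialect or {})
    tcol = dialect.pop("timestamp_column", "timestamp")
    vcol = dialect.pop("value_column", value_col)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, **{k: v for k, v in dialect.items()
                              if k in ("sep", "comment", "skiprows")})
    if len(df) == 0:
        raise SeriesValidationError(f"{path}: empty series")
    for col in (tcol, vcol):
        if col not in df.columns:
            raise SeriesValidationError(f"{path}: missing required column {col!r}")
    idx = _parse_timestamps(df[tcol], path)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise SeriesValidationError(f"{path}: duplicate timestamp {dup} (corrupt export?)")
    out = pd.DataFrame({value_col: pd.to_numeric(df[vcol]).to_numpy()}, index=idx)
    if not out.index.is_monotonic_increasing:
        logger.warning("%s: rows out of order; sorting by timestamp", path)
        out = out.sort_index()
    return out, dialect


def read_light_series(path, dialect: dict | None = None, logger_id: str | None = None,
                      leg: str = "unknown", fix_interval: int | None = None) -> LightSeries:
    """Read a light CSV into a validated :class:`LightSeries`.

    ``dialect`` may override ``timestamp_column`` / ``value_column`` and basic
    ``pandas.read_csv`` options.  The fix interval is inferred from the median
    timestamp step when not given.
    """
    df, _ = _read_frame(path, "light", dialect)
    if fix_interval is None:
        fix_interval = _infer_interval_minutes(df.index)
    lid = logger_id if logger_id is not None else Path(path).stem
    series = LightSeries(logger_id=lid, leg=leg, data=df, fix_interval=fix_interval)
    logger.info("read %d light fixes from %s (interval %d min)", len(series), path, fix_interval)
    return series


def read_immersion_series(path, dialect: dict | None = None, logger_id: str | None = None,
                          leg: str = "unknown", fix_interval: int | None = None,
                          scale_max: int = WET_SCALE_MAX) -> ImmersionSeries:
    """Read an immersion CSV into a validated :class:`ImmersionSeries`."""
    df, _ = _read_frame(path, "wet_count", dialect)
    if fix_interval is None:
        fix_interval = _infer_interval_minutes(df.index)
    lid = logger_id if logger_id is not None else Path(path).stem
    series = ImmersionSeries(logger_id=lid, leg=leg, data=df, fix_interval=fix_interval,
                             scale_max=scale_max)
    logger.info("read %d immersion fixes from %s (interval %d min)", len(series), path, fix_interval)
    return series


def write_light_series(series: LightSeries, path) -> None:
    df = pd.DataFrame({"timestamp": series.times.strftime("%Y-%m-%dT%H:%M:%SZ"),
                       "light": series.light})
    df.to_csv(path, index=False)


def write_immersion_series(series: ImmersionSeries, path) -> None:
    df = pd.DataFrame({"timestamp": series.times.strftime("%Y-%m-%dT%H:%M:%SZ"),
                       "wet_count": series.wet_count})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline reports
# ---------------------------------------------------------------------------

MOLT_COLUMNS = ["start_date", "end_date", "duration_days", "iteration", "threshold_used", "basis"]
ACTIVITY_COLUMNS = ["date", "prop_flight", "prop_flight5", "n_daylight_fixes"]
POSITION_COLUMNS = ["date", "lon", "lat", "lat_quality"]


def write_reports(activity: pd.DataFrame | None, molts: list, positions: pd.DataFrame | None,
                  out_dir) -> dict[str, Path]:
    """Write the standard pipeline outputs (activity, molt, positions CSVs).

    Molt windows are written with ISO-8601 dates; every file round-trips
    through :func:`read_reports`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    mrows = []
    for w in molts or []:
        mrows.append({
            "start_date": pd.Timestamp(w.start_date).date().isoformat(),
            "end_date": pd.Timestamp(w.end_date).date().isoformat(),
            "duration_days": int(w.duration_days),
            "iteration": int(w.iteration),
            "threshold_used": float(w.threshold_used),
            "basis": w.basis,
        })
    mpath = out_dir / "molt_windows.csv"
    pd.DataFrame(mrows, columns=MOLT_COLUMNS).to_csv(mpath, index=False)
    written["molt"] = mpath

    if activity is not None:
        apath = out_dir / "daily_activity.csv"
        adf = activity.copy()
        adf["date"] = pd.DatetimeIndex(adf["date"]).strftime("%Y-%m-%d")
        adf[ACTIVITY_COLUMNS].to_csv(apath, index=False)
        written["activity"] = apath

    if positions is not None:
        ppath = out_dir / "positions.csv"
        pdf = positions.copy()
        pdf["date"] = pd.DatetimeIndex(pdf["date"]).strftime("%Y-%m-%d")
        pdf[POSITION_COLUMNS].to_csv(ppath, index=False)
        written["positions"] = ppath

    logger.info("wrote reports to %s: %s", out_dir, sorted(written))
    return written


def read_reports(out_dir) -> dict:
    """Read back the CSVs written by :func:`write_reports`."""
    out_dir = Path(out_dir)
    out: dict = {}
    mpath = out_dir / "molt_windows.csv"
    if mpath.exists():
        out["molt"] = pd.read_csv(mpath, parse_dates=["start_date", "end_date"])
    apath = out_dir / "daily_activity.csv"
    if apath.exists():
        out["activity"] = pd.read_csv(apath, parse_dates=["date"])
    ppath = out_dir / "positions.csv"
    if ppath.exists():
        out["positions"] = pd.read_csv(ppath, parse_dates=["date"])
    return out
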