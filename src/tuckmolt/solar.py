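"""Solar geometry for geolocator analysis.

Implements the NOAA (Meeus-derived) low-precision solar ephemeris: apparent
declination, the equation of time and solar elevation for any UTC instant and
position.  Accuracy is a few hundredths of a degree over 1950-2050, ample for
the half-degree tolerances that matter here (twilight thresholds at -6 and -3
degrees elevation).

Elevations are *refracted* by default (NOAA refraction model, ~0.5 deg at the
horizon); pass ``refracted=False`` for the geometric altitude.  Threshold
geolocation works throughout on geometric altitudes because the calibrated
zenith absorbs refraction, attenuation and sensor response in one constant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "julian_century",
    "sun_declination_eqtime",
    "solar_elevation",
    "elevation_for_times",
    "twilight_times",
]

_DEG = np.pi / 180.0


def _to_unix_seconds(times) -> np.ndarray:
    """Coerce datetime-like input (scalar, array, DatetimeIndex) to float64 unix seconds."""
    if isinstance(times, (pd.Timestamp, str)):
        times = pd.DatetimeIndex([times])
    if isinstance(times, pd.DatetimeIndex):
        if times.tz is not None:
            times = times.tz_convert("UTC").tz_localize(None)
        arr = times.values
    else:
        arr = np.asarray(times)
    return arr.astype("datetime64[s]").astype(np.float64)


def julian_century(times) -> np.ndarray:
    """Julian centuries since J2000.0 for UTC datetimes."""
    secs = _to_unix_seconds(times)
    jd = secs / 86400.0 + 2440587.5
    return (jd - 2451545.0) / 36525.0


def sun_declination_eqtime(times):
    """Apparent solar declination (degrees) and equation of time (minutes).

    NOAA's formulation of Meeus' low-precision solar position.
    """
    t = julian_century(times)
    l0 = np.mod(280.46646 + t * (36000.76983 + t * 0.0003032), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = m * _DEG
    c = (
        np.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + np.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = (125.04 - 1934.136 * t) * _DEG
    app_long = true_long - 0.00569 - 0.00478 * np.sin(omega)
    # mean then corrected obliquity of the ecliptic
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = (eps0 + 0.00256 * np.cos(omega)) * _DEG
    decl = np.arcsin(np.sin(eps) * np.sin(app_long * _DEG)) / _DEG

    y = np.tan(eps / 2.0) ** 2
    l0rad = l0 * _DEG
    eqtime = 4.0 / _DEG * (
        y * np.sin(2 * l0rad)
        - 2.0 * e * np.sin(mrad)
        + 4.0 * e * y * np.sin(mrad) * np.cos(2 * l0rad)
        - 0.5 * y * y * np.sin(4 * l0rad)
        - 1.25 * e * e * np.sin(2 * mrad)
    )
    return decl, eqtime


def _refraction_correction(elev_deg: np.ndarray) -> np.ndarray:
    """NOAA atmospheric refraction correction (degrees) as a function of geometric elevation."""
    e = np.asarray(elev_deg, dtype=float)
    corr = np.zeros_like(e)
    tan_e = np.tan(np.clip(e, -89.9, 89.9) * _DEG)
    with np.errstate(divide="ignore", invalid="ignore"):
        hi = (e > 5.0) & (e <= 85.0)
        corr = np.where(
            hi, (58.1 / tan_e - 0.07 / tan_e**3 + 0.000086 / tan_e**5) / 3600.0, corr
        )
        mid = (e > -0.575) & (e <= 5.0)
        corr = np.where(
            mid,
            (1735.0 + e * (-518.2 + e * (103.4 + e * (-12.79 + e * 0.711)))) / 3600.0,
            corr,
        )
        lo = e <= -0.575
        corr = np.where(lo, (-20.772 / tan_e) / 3600.0, corr)
    return corr


def solar_elevation(times, lat, lon, refracted: bool = True):
    """Solar elevation (degrees above horizon) at UTC ``times`` for a position.

    Parameters
    ----------
    times : datetime-like scalar or array (UTC)
    lat, lon : degrees, scalar or arrays broadcastable against ``times``
    refracted : include atmospheric refraction (default True)

    Returns
    -------
    ndarray (or scalar for scalar input) of elevations in [-90, 90].
    """
    scalar = np.isscalar(lat) and not hasattr(times, "__len__") and not isinstance(times, pd.DatetimeIndex)
    secs = _to_unix_seconds(times)
    decl, eqtime = sun_declination_eqtime(times)
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    minutes = np.mod(secs, 86400.0) / 60.0
    tst = np.mod(minutes + eqtime + 4.0 * lon, 1440.0)
    ha = (tst / 4.0) - 180.0  # degrees, negative before solar noon
    latr, declr, har = lat * _DEG, decl * _DEG, ha * _DEG
    cos_zen = np.sin(latr) * np.sin(declr) + np.cos(latr) * np.cos(declr) * np.cos(har)
    elev = 90.0 - np.arccos(np.clip(cos_zen, -1.0, 1.0)) / _DEG
    if refracted:
        elev = elev + _refraction_correction(elev)
    elev = np.clip(elev, -90.0, 90.0)
    if np.ndim(elev) == 0:
        return float(elev)
    if scalar and elev.size == 1:
        return float(elev[0])
    return elev


def elevation_for_times(times: pd.DatetimeIndex, positions: pd.DataFrame | None = None,
                        colony: tuple[float, float] | None = None,
                        refracted: bool = True) -> np.ndarray:
    """Elevation for each timestamp using that calendar day's position estimate.

    ``positions`` is a DataFrame with columns ``date`` (datetime-like, daily),
    ``lat``, ``lon``; a timestamp whose day is missing falls back to the nearest
    available day.  With ``positions=None`` the fixed ``colony`` (lat, lon) is
    used throughout.
    """
    times = pd.DatetimeIndex(times)
    if positions is None or len(positions) == 0:
        if colony is None:
            raise ValueError("no positions available: provide a track or a colony location")
        return solar_elevation(times, colony[0], colony[1], refracted=refracted)
    pos = positions.dropna(subset=["lat", "lon"]).copy()
    if len(pos) == 0:
        if colony is not None:
            return solar_elevation(times, colony[0], colony[1], refracted=refracted)
        raise ValueError("no positions available: provide a track or a colony location")
    pos_days = pd.DatetimeIndex(pos["date"]).normalize().asi8
    order = np.argsort(pos_days)
    pos_days = pos_days[order]
    plat = pos["lat"].to_numpy()[order]
    plon = pos["lon"].to_numpy()[order]
    fix_days = times.normalize().asi8
    # nearest available day (left/right midpoint rule)
    idx = np.searchsorted(pos_days, fix_days)
    idx = np.clip(idx, 1, len(pos_days) - 1)
    left_closer = (fix_days - pos_days[idx - 1]) <= (pos_days[idx] - fix_days)
    idx = np.where(left_closer, idx - 1, idx)
    if len(pos_days) == 1:
        idx = np.zeros(len(times), dtype=int)
    return solar_elevation(times, plat[idx], plon[idx], refracted=refracted)


def twilight_times(date, lat: float, lon: float, zenith: float) -> tuple[pd.Timestamp | None, pd.Timestamp | None]:
    """Times at which the sun crosses ``90 - zenith`` degrees geometric elevation.

    Returns (rise, set) for the daylight period whose local solar noon falls on
    ``date`` (UTC calendar date of noon); either may be None at extreme
    latitudes (polar day/night at that zenith).  This is the forward model used
    to exercise the threshold-geolocation inversion.
    """
    target = 90.0 - zenith
    day = pd.Timestamp(date).normalize()
    # local solar noon in UTC, then scan +-12h around it at 1-min resolution
    noon_guess = day + pd.Timedelta(hours=12) - pd.Timedelta(hours=lon / 15.0)
    grid = pd.date_range(noon_guess - pd.Timedelta(hours=12),
                         noon_guess + pd.Timedelta(hours=12), freq="60s")
    elev = solar_elevation(grid, lat, lon, refracted=False)
    above = elev > target
    if above.all() or not above.any():
        return None, None
    crossings = np.flatnonzero(np.diff(above.astype(int)))

    def _refine(i: int) -> pd.Timestamp:
        e0, e1 = elev[i], elev[i + 1]
        frac = (target - e0) / (e1 - e0)
        return grid[i] + pd.Timedelta(seconds=60.0 * float(frac))

    rise = None
    sett = None
    for i in crossings:
        if elev[i + 1] > elev[i] and rise is None:
            rise = _refine(i)
        elif elev[i + 1] < elev[i]:
            sett = _refine(i)
    return rise, sett
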