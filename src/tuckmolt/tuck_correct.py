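"""Leg-tuck detection from light anomalies and immersion correction.

An alcid resting on the water with its leg (and logger) tucked into the
plumage reads *dry* and *dark* while the bird is actually sitting at the sea
surface in daylight.  The tell-tale is therefore light that is anomalously low
for the prevailing solar elevation.  We fit a monotone model of scaled light
(raw/64) against solar elevation on a seeded subset of fixes, flag daylight
fixes whose reading falls more than twice the residual SD below the model
prediction, extend each flagged run by one fix on either side (bout edges are
only partially tucked, so their maximum light is not anomalous), and force the
overlapping immersion bins to fully wet.

The correction is only meaningful in daylight: below -6 deg solar elevation
the expected light is zero and a dark logger carries no tucking information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .geo_io import ImmersionSeries, LightSeries

logger = logging.getLogger(__name__)

# TuckMask flag codes
NOT_TUCKED = 0
TUCKED_LIGHT = 1
TUCKED_NEIGHBOR = 2
NOT_ASSESSABLE_NIGHT = 3
FLAG_LABELS = {
    NOT_TUCKED: "not_tucked",
    TUCKED_LIGHT: "tucked_light",
    TUCKED_NEIGHBOR: "tucked_neighbor",
    NOT_ASSESSABLE_NIGHT: "not_assessable_night",
}

NIGHT_ELEVATION_DEG = -6.0      # below this the rule cannot be assessed
DARK_FLOOR = 0.02               # gate: prediction - 2 SD must exceed this


class FitError(RuntimeError):
    pass


@dataclass
class LightModel:
    """Monotone map from solar elevation (deg) to expected scaled light (0-1)."""

    x_: np.ndarray            # elevation knots (increasing)
    y_: np.ndarray            # fitted scaled light at knots (nondecreasing, in [0,1])
    residual_sd: float
    subset_n: int
    seed: int | None = None

    def predict(self, elevations) -> np.ndarray:
        e = np.asarray(elevations, dtype=float)
        return np.clip(np.interp(e, self.x_, self.y_), 0.0, 1.0)

    @classmethod
    def from_table(cls, elevations, expected, residual_sd: float) -> "LightModel":
        """Construct directly from a lookup table (mainly for testing/audit)."""
        x = np.asarray(elevations, dtype=float)
        y = np.asarray(expected, dtype=float)
        order = np.argsort(x)
        return cls(x_=x[order], y_=np.maximum.accumulate(y[order]),
                   residual_sd=float(residual_sd), subset_n=len(x))


@dataclass
class TuckMask:
    """Per-fix tucking classification aligned to a light series."""

    times: pd.DatetimeIndex
    flags: np.ndarray         # int8 codes, see FLAG_LABELS
    fix_interval: int         # minutes

    def __len__(self) -> int:
        return len(self.flags)

    @property
    def labels(self) -> np.ndarray:
        return np.array([FLAG_LABELS[f] for f in self.flags])

    @property
    def tucked(self) -> np.ndarray:
        """Boolean: flagged as tucking (light-informed or neighbour)."""
        return (self.flags == TUCKED_LIGHT) | (self.flags == TUCKED_NEIGHBOR)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.times, "flag": self.labels})


def scale_light(light: LightSeries | np.ndarray) -> np.ndarray:
    """Scale raw 0-64 light readings to [0, 1]."""
    raw = light.light if isinstance(light, LightSeries) else np.asarray(light, dtype=float)
    return raw / 64.0


def fit_light_model(scaled_light: np.ndarray, elevations: np.ndarray,
                    subset_n: int = 100_000, seed: int | None = 0) -> LightModel:
    """Fit the expected-light-given-elevation model.

    Isotonic (monotone nondecreasing) least-squares regression of scaled light
    on solar elevation over a uniform random subset of at most ``subset_n``
    fixes.  ``residual_sd`` is the SD of observed minus predicted over the
    fitted subset.  Deterministic given ``seed``.
    """
    y = np.asarray(scaled_light, dtype=float)
    x = np.asarray(elevations, dtype=float)
    if len(y) != len(x):
        raise ValueError("scaled light and elevations differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) == 0 or np.ptp(x) < 1e-9:
        raise FitError("degenerate elevations: cannot fit light model")
    if len(x) > subset_n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(x), size=subset_n, replace=False)
        x, y = x[idx], y[idx]
    iso = IsotonicRegression(increasing=True, y_min=0.0, y_max=1.0, out_of_bounds="clip")
    pred = iso.fit_transform(x, y)
    resid_sd = float(np.std(y - pred))
    if resid_sd <= 0:
        resid_sd = 1e-6  # noiseless input; keep the 2-SD rule well defined
    # compress to unique knots for fast interpolation
    xs = np.asarray(iso.X_thresholds_, dtype=float)
    ys = np.asarray(iso.y_thresholds_, dtype=float)
    model = LightModel(x_=xs, y_=ys, residual_sd=resid_sd, subset_n=len(x), seed=seed)
    logger.info("light model fitted on %d fixes, residual SD %.4f", len(x), resid_sd)
    return model


def flag_tucking(scaled_light: np.ndarray, model: LightModel, elevations: np.ndarray,
                 times: pd.DatetimeIndex | None = None, fix_interval: int = 5) -> TuckMask:
    """Classify each fix as tucking / not / night-unassessable.

    A fix is ``tucked_light`` when (a) the sun is above -6 deg, (b) the
    observed scaled light sits more than 2 residual SDs below the model
    prediction, and (c) the prediction minus 2 SD is itself above a small
    floor (0.02) so the rule is not vacuous near twilight.  The single fix on
    either side of each maximal tucked run becomes ``tucked_neighbor``.
    """
    obs = np.asarray(scaled_light, dtype=float)
    elev = np.asarray(elevations, dtype=float)
    if len(obs) != len(elev):
        raise ValueError(f"length mismatch: {len(obs)} light vs {len(elev)} elevations")
    pred = model.predict(elev)
    day = elev > NIGHT_ELEVATION_DEG
    margin = pred - 2.0 * model.residual_sd
    tucked = day & (pred - obs > 2.0 * model.residual_sd) & (margin > DARK_FLOOR)
    flags = np.full(len(obs), NOT_TUCKED, dtype=np.int8)
    flags[~day] = NOT_ASSESSABLE_NIGHT
    flags[tucked] = TUCKED_LIGHT
    # one neighbour on each side of each maximal tucked_light run
    before = np.zeros_like(tucked)
    before[:-1] = tucked[1:] & ~tucked[:-1]
    after = np.zeros_like(tucked)
    after[1:] = tucked[:-1] & ~tucked[1:]
    neighbor = (before | after) & ~tucked & day
    flags[neighbor] = TUCKED_NEIGHBOR
    if times is None:
        times = pd.RangeIndex(len(obs))
    n_flag = int(tucked.sum() + neighbor.sum())
    logger.info("flagged %d/%d fixes as tucking (%d light-informed)",
                n_flag, len(obs), int(tucked.sum()))
    return TuckMask(times=pd.DatetimeIndex(times) if not isinstance(times, pd.RangeIndex) else times,
                    flags=flags, fix_interval=fix_interval)


def apply_tuck_correction(imm: ImmersionSeries, mask: TuckMask) -> ImmersionSeries:
    """Set immersion bins overlapping any tucked fix to fully wet.

    A bin [t, t+interval) is corrected when any ``tucked_*`` light fix
    interval overlaps it (light fixes may be finer than immersion bins).
    Monotone (wet counts never decrease) and idempotent.  The two series must
    be alignable: grid offset beyond one immersion interval is an error.
    """
    if not isinstance(mask.times, pd.DatetimeIndex):
        raise ValueError("mask must carry timestamps to correct an immersion series")
    imm_t = imm.times.asi8
    imm_dt = imm.fix_interval * 60 * 1_000_000_000
    light_dt = mask.fix_interval * 60 * 1_000_000_000
    flagged_t = mask.times.asi8[mask.tucked]
    # alignment sanity: nearest immersion bin start within one immersion interval
    overlap_lo = imm_t[0] - light_dt
    overlap_hi = imm_t[-1] + imm_dt
    in_span = (flagged_t >= overlap_lo) & (flagged_t < overlap_hi)
    if len(mask.times):
        m_all = mask.times.asi8
        m_span = m_all[(m_all >= imm_t[0] - imm_dt) & (m_all <= imm_t[-1] + imm_dt)]
        if len(m_span) == 0:
            raise ValueError("light and immersion series are unalignable "
                             "(no mask fix within one interval of the immersion span)")
        if len(m_span):
            pos = np.searchsorted(imm_t, m_span)
            pos = np.clip(pos, 1, len(imm_t) - 1) if len(imm_t) > 1 else np.zeros(len(m_span), int)
            near = np.minimum(np.abs(m_span - imm_t[np.maximum(pos - 1, 0)]),
                              np.abs(imm_t[np.minimum(pos, len(imm_t) - 1)] - m_span))
            if near.min() > imm_dt:
                raise ValueError("light and immersion series are unalignable "
                                 "(offset exceeds one fix interval)")
    flagged_t = flagged_t[in_span]
    corrected = imm.data.copy()
    wet = corrected["wet_count"].to_numpy(dtype=float)
    # bins whose [start, start+imm_dt) intersects a flagged [t0, t0+light_dt):
    # bin starts in (t0 - imm_dt, t0 + light_dt)
    j0 = np.searchsorted(imm_t, flagged_t - imm_dt, side="right")
    j1 = np.searchsorted(imm_t, flagged_t + light_dt, side="left")
    bump = np.zeros(len(wet) + 1, dtype=np.int64)
    np.add.at(bump, j0, 1)
    np.add.at(bump, j1, -1)
    hit = np.cumsum(bump[:-1]) > 0
    wet[hit] = imm.scale_max
    corrected["wet_count"] = wet
    logger.info("tuck correction set %d/%d immersion bins to fully wet", int(hit.sum()), len(wet))
    return ImmersionSeries(logger_id=imm.logger_id, leg=imm.leg, data=corrected,
                           fix_interval=imm.fix_interval, scale_max=imm.scale_max)
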