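"""End-to-end orchestration for single- and dual-logger birds.

Chain for a dual-equipped bird: threshold geolocation from one logger's light
(twilights -> editing -> zenith calibration -> daily positions -> equinox
smoothing), solar elevations for every fix from the daily position, per-leg
leg-tuck correction of the immersion series, pairwise-max fusion in both
directions, daily flight proportions gated at -3 deg solar elevation within
the non-breeding season, and the incrementing-threshold molt scan on each
fusion basis.  The single-logger chain is identical minus the fusion step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dual_combine, geolocate, molt_detect, solar, tuck_correct
from .geo_io import ImmersionSeries, LightSeries
from .molt_detect import MoltWindow

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Every pipeline constant, named, with its standard default."""

    light_threshold: float = 1.0          # twilight crossing level (0-64 scale)
    twilight_window_days: int = 4
    twilight_outlier_mins: float = 45.0
    twilight_stationary_mins: float = 15.0
    zenith_min: float = 90.0
    zenith_max: float = 100.0
    zenith_step: float = 0.25
    loess_span: float = 0.3
    night_gate_deg: float = -6.0          # below: tucking not assessable from light
    activity_gate_deg: float = -3.0       # below: bins excluded from daily proportions
    model_subset_n: int = 100_000         # light-model fitting subset
    threshold_step: float = 0.0002
    min_molt_days: int = 30
    threshold_cap: float = 0.01
    season_start: tuple[int, int] = (8, 1)   # non-breeding analysis window
    season_end: tuple[int, int] = (4, 30)
    positions: str = "geolocate"          # "geolocate" | "colony"
    seed: int = 0


@dataclass
class BasisResult:
    activity: pd.DataFrame
    molts: list[MoltWindow]


@dataclass
class PipelineResult:
    bird_id: str
    mode: str                                   # "dual" | "single"
    basis_results: dict[str, BasisResult]
    positions: pd.DataFrame | None
    zenith: float | None
    dry_summary: dict[str, float]               # percent of daylight time dry
    molt_table: pd.DataFrame                    # per-iteration ranges across bases

    @property
    def molts(self) -> list[MoltWindow]:
        out = []
        for br in self.basis_results.values():
            out.extend(br.molts)
        return out


def _in_season(dates: pd.DatetimeIndex, config: PipelineConfig) -> np.ndarray:
    key = dates.month * 100 + dates.day
    k0 = config.season_start[0] * 100 + config.season_start[1]
    k1 = config.season_end[0] * 100 + config.season_end[1]
    if k0 <= k1:
        return ((key >= k0) & (key <= k1)).to_numpy() if hasattr(key, "to_numpy") else (key >= k0) & (key <= k1)
    res = (key >= k0) | (key <= k1)
    return res.to_numpy() if hasattr(res, "to_numpy") else res


def geolocate_positions(light: LightSeries, colony: tuple[float, float],
                        config: PipelineConfig) -> tuple[pd.DataFrame | None, float | None]:
    """Daily smoothed positions (and calibrated zenith) from one light series."""
    events = geolocate.detect_twilights(light, config.light_threshold)
    events = geolocate.edit_twilights(events, window=config.twilight_window_days,
                                      outlier_mins=config.twilight_outlier_mins,
                                      stationary_mins=config.twilight_stationary_mins)
    search = np.arange(config.zenith_min, config.zenith_max + 1e-9, config.zenith_step)
    try:
        cal = geolocate.calibrate_zenith(events, search=search)
    except geolocate.CalibrationError as err:
        logger.warning("zenith calibration failed (%s); falling back to colony position", err)
        return None, None
    fixes = geolocate.positions_from_twilights(events, cal.zenith)
    fixes = geolocate.smooth_latitudes(fixes, span=config.loess_span)
    logger.info("geolocation: %d twilights -> %d daily fixes, zenith %.2f",
                len(events), len(fixes), cal.zenith)
    return fixes, cal.zenith


def _correct_leg(light: LightSeries, imm: ImmersionSeries,
                 positions: pd.DataFrame | None, colony: tuple[float, float],
                 config: PipelineConfig) -> tuple[ImmersionSeries, tuck_correct.TuckMask]:
    elev = solar.elevation_for_times(light.times, positions=positions, colony=colony)
    scaled = tuck_correct.scale_light(light)
    model = tuck_correct.fit_light_model(scaled, elev, subset_n=config.model_subset_n,
                                         seed=config.seed)
    mask = tuck_correct.flag_tucking(scaled, model, elev, times=light.times,
                                     fix_interval=light.fix_interval)
    corrected = tuck_correct.apply_tuck_correction(imm, mask)
    return corrected, mask


def _activity(imm: ImmersionSeries, positions: pd.DataFrame | None,
              colony: tuple[float, float], config: PipelineConfig) -> pd.DataFrame:
    elev = solar.elevation_for_times(imm.times, positions=positions, colony=colony)
    days = molt_detect.daily_flight_proportion(imm, elev, min_elevation=config.activity_gate_deg)
    days = days[_in_season(pd.DatetimeIndex(days["date"]), config)].reset_index(drop=True)
    return molt_detect.rolling_mean5(days)


def _mean_dry_pct(imm: ImmersionSeries, positions, colony, config) -> float:
    elev = solar.elevation_for_times(imm.times, positions=positions, colony=colony)
    days = molt_detect.daily_flight_proportion(imm, elev, min_elevation=config.activity_gate_deg)
    return float(np.nanmean(days["prop_flight"].to_numpy()) * 100.0)


def _molt_table(basis_results: dict[str, BasisResult]) -> pd.DataFrame:
    """Per-iteration start/duration ranges across fusion bases (report format)."""
    rows = []
    iters = sorted({w.iteration for br in basis_results.values() for w in br.molts})
    for it in iters:
        windows = [w for br in basis_results.values() for w in br.molts if w.iteration == it]
        starts = [w.start_date for w in windows]
        durs = [w.duration_days for w in windows]
        rows.append({
            "iteration": it,
            "n_bases": len(windows),
            "start_min": min(starts), "start_max": max(starts),
            "duration_min": min(durs), "duration_max": max(durs),
        })
    return pd.DataFrame(rows, columns=["iteration", "n_bases", "start_min", "start_max",
                                       "duration_min", "duration_max"])


def run_dual(left_light: LightSeries, left_imm: ImmersionSeries,
             right_light: LightSeries, right_imm: ImmersionSeries,
             colony: tuple[float, float], config: PipelineConfig | None = None,
             bird_id: str = "bird") -> PipelineResult:
    """Full dual-equipped chain; molt windows reported on both fusion bases."""
    config = config or PipelineConfig()
    # geolocate from the finer-interval logger's light
    base_light = left_light if left_light.fix_interval <= right_light.fix_interval else right_light
    positions, zenith = (None, None)
    if config.positions == "geolocate":
        positions, zenith = geolocate_positions(base_light, colony, config)

    corr_left, _ = _correct_leg(left_light, left_imm, positions, colony, config)
    corr_right, _ = _correct_leg(right_light, right_imm, positions, colony, config)
    combined = dual_combine.combine_both_directions(corr_left, corr_right)

    basis_results = {}
    for basis, series in combined.items():
        act = _activity(series, positions, colony, config)
        molts = molt_detect.detect_molts(act, step=config.threshold_step,
                                         min_days=config.min_molt_days,
                                         cap=config.threshold_cap, basis=basis)
        basis_results[basis] = BasisResult(activity=act, molts=molts)

    dry = {
        "raw_pct": float(np.mean([_mean_dry_pct(s, positions, colony, config)
                                  for s in (left_imm, right_imm)])),
        "light_adjusted_pct": float(np.mean([_mean_dry_pct(s, positions, colony, config)
                                             for s in (corr_left, corr_right)])),
        "combined_pct": float(np.mean([_mean_dry_pct(s, positions, colony, config)
                                       for s in combined.values()])),
    }
    logger.info("dry %% of daylight (raw/light-adjusted/combined): %.1f / %.1f / %.1f",
                dry["raw_pct"], dry["light_adjusted_pct"], dry["combined_pct"])
    return PipelineResult(bird_id=bird_id, mode="dual", basis_results=basis_results,
                          positions=positions, zenith=zenith, dry_summary=dry,
                          molt_table=_molt_table(basis_results))


def run_single(light: LightSeries, imm: ImmersionSeries,
               colony: tuple[float, float], config: PipelineConfig | None = None,
               bird_id: str = "bird") -> PipelineResult:
    """Single-logger chain: the dual chain without the fusion step."""
    config = config or PipelineConfig()
    positions, zenith = (None, None)
    if config.positions == "geolocate":
        positions, zenith = geolocate_positions(light, colony, config)
    corrected, _ = _correct_leg(light, imm, positions, colony, config)
    act = _activity(corrected, positions, colony, config)
    molts = molt_detect.detect_molts(act, step=config.threshold_step,
                                     min_days=config.min_molt_days,
                                     cap=config.threshold_cap, basis="single")
    basis_results = {"single": BasisResult(activity=act, molts=molts)}
    dry = {
        "raw_pct": _mean_dry_pct(imm, positions, colony, config),
        "light_adjusted_pct": _mean_dry_pct(corrected, positions, colony, config),
    }
    logger.info("dry %% of daylight (raw/light-adjusted): %.1f / %.1f",
                dry["raw_pct"], dry["light_adjusted_pct"])
    return PipelineResult(bird_id=bird_id, mode="single", basis_results=basis_results,
                          positions=positions, zenith=zenith, dry_summary=dry,
                          molt_table=_molt_table(basis_results))
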