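import numpy as np
import pandas as pd
import pytest

from tuckmolt import geolocate, solar
from tuckmolt.geolocate import TwilightEvent

from conftest import make_light_series, square_wave_light


def forward_twilights(lat, lon, zenith, start, n_days):
    """Forward-model oracle: exact threshold-crossing times from the ephemeris."""
    events = []
    for d in pd.date_range(start, periods=n_days, freq="D"):
        rise, sett = solar.twilight_times(d, lat, lon, zenith)
        if rise is not None:
            events.append(TwilightEvent(rise, "rise"))
        if sett is not None:
            events.append(TwilightEvent(sett, "set"))
    events.sort(key=lambda e: e.time)
    return events


class TestDetectTwilights:
    def test_square_wave_one_pair_per_day(self):
        light = square_wave_light(n_days=10)
        events = geolocate.detect_twilights(light)
        kinds = [e.kind for e in events]
        assert kinds.count("rise") == 10 and kinds.count("set") == 10

    def test_all_zero_series_empty(self, caplog):
        light = make_light_series(np.zeros(288 * 3, dtype=int))
        with caplog.at_level("WARNING"):
            assert geolocate.detect_twilights(light) == []

    def test_crossing_time_interpolated(self):
        # 0 at 05:55 -> 4 at 06:00 across the threshold of 1: the crossing is
        # linearly interpolated 1/4 of the way through that step (05:56:15)
        light = square_wave_light(n_days=3, level=4)
        ev = geolocate.detect_twilights(light)
        rises = [e for e in ev if e.kind == "rise"]
        assert rises[0].time.minute == 56 and rises[0].time.second == 15

    def test_short_dark_dip_is_not_a_twilight(self):
        light = square_wave_light(n_days=5)
        v = light.data["light"].to_numpy().copy()
        # a 30-min shading event mid-day (e.g. a tucked leg)
        noon = np.flatnonzero((light.times.hour == 12) & (light.times.minute == 0))
        for i in noon:
            v[i:i + 6] = 0
        dipped = make_light_series(v)
        assert len(geolocate.detect_twilights(dipped)) == len(geolocate.detect_twilights(light))

    def test_rendered_light_crossings_near_oracle(self, sim_bird):
        """Twilights detected from simulator-rendered light sit within one fix
        interval of the ephemeris crossing time at the true position."""
        light = sim_bird["light"]["left"]
        events = [e for e in geolocate.detect_twilights(light)]
        pos = sim_bird["trace"].positions.set_index("date")
        # effective zenith of the renderer: light crosses 1 near civil twilight
        errs = []
        for ev in events[2:40]:
            day = ev.time.normalize()
            row = pos.loc[day]
            rise, sett = solar.twilight_times(day, row.lat, row.lon, 96.3)
            oracle = rise if ev.kind == "rise" else sett
            if oracle is not None:
                errs.append(abs((ev.time - oracle).total_seconds()) / 60)
        assert np.median(errs) <= 5.0


class TestEditTwilights:
    @staticmethod
    def _regular(n=20, rise_h=6, set_h=18):
        ev = []
        for d in pd.date_range("2010-08-01", periods=n, freq="D"):
            ev.append(TwilightEvent(d + pd.Timedelta(hours=rise_h), "rise"))
            ev.append(TwilightEvent(d + pd.Timedelta(hours=set_h), "set"))
        return ev

    def test_regular_events_all_kept(self):
        out = geolocate.edit_twilights(self._regular())
        assert all(e.status == "kept" for e in out)

    def test_displaced_event_adjusted_to_neighborhood_median(self):
        ev = self._regular()
        i = 10  # a rise event
        assert ev[i].kind == "rise"
        ev[i] = TwilightEvent(ev[i].time + pd.Timedelta(minutes=120), "rise")
        out = geolocate.edit_twilights(ev)
        assert out[i].status == "adjusted"
        # brute-force oracle: median time-of-day of same-kind events within 4 days
        neigh = [e.time for j, e in enumerate(ev)
                 if e.kind == "rise" and j != i
                 and abs((e.time.normalize() - ev[i].time.normalize()).days) <= 4]
        med = float(np.median([(t - t.normalize()).total_seconds() / 60 for t in neigh]))
        got = (out[i].time - out[i].time.normalize()).total_seconds() / 60
        assert got == pytest.approx(med, abs=1e-6)
        assert out[i].original_time == ev[i].time

    def test_displaced_event_with_disagreeing_neighbors_deleted(self):
        ev = self._regular()
        # neighbors drift (genuine movement): rise time shifts 20 min/day
        ev = []
        for k, d in enumerate(pd.date_range("2010-08-01", periods=20, freq="D")):
            ev.append(TwilightEvent(d + pd.Timedelta(hours=6, minutes=20 * k), "rise"))
            ev.append(TwilightEvent(d + pd.Timedelta(hours=18), "set"))
        ev.sort(key=lambda e: e.time)
        out = geolocate.edit_twilights(ev)
        # drifting events deviate >45 min from the window median but neighbors
        # disagree by >15 min, so they are deleted rather than adjusted
        assert any(e.status == "deleted" for e in out)
        assert not any(e.status == "adjusted" for e in out)

    def test_fewer_events_than_window_unchanged(self, caplog):
        ev = self._regular(n=3)
        with caplog.at_level("WARNING"):
            out = geolocate.edit_twilights(ev, window=10)
        assert out == ev

    def test_editing_partitions_and_never_adds(self):
        ev = self._regular()
        ev[7] = TwilightEvent(ev[7].time + pd.Timedelta(minutes=90), ev[7].kind)
        out = geolocate.edit_twilights(ev)
        assert len(out) == len(ev)
        assert {e.status for e in out} <= {"kept", "adjusted", "deleted"}


class TestPositions:
    def test_symmetric_pair_gives_zero_longitude(self):
        # mid-April: equation of time ~ 0, so the midpoint rule is exact
        rise = TwilightEvent(pd.Timestamp("2010-04-15 06:00"), "rise")
        sett = TwilightEvent(pd.Timestamp("2010-04-15 18:00"), "set")
        fix = geolocate.position_from_twilight_pair(rise, sett, 96.0)
        assert abs(fix["lon"]) < 1.0

    def test_equinox_12h_day_is_degenerate(self):
        rise = TwilightEvent(pd.Timestamp("2010-03-20 06:00"), "rise")
        sett = TwilightEvent(pd.Timestamp("2010-03-20 18:00"), "set")
        fix = geolocate.position_from_twilight_pair(rise, sett, 96.0)
        assert fix["lat_quality"] == "undefined" and np.isnan(fix["lat"])

    def test_set_before_rise_rejected(self):
        rise = TwilightEvent(pd.Timestamp("2010-04-15 18:00"), "rise")
        sett = TwilightEvent(pd.Timestamp("2010-04-15 06:00"), "set")
        with pytest.raises(ValueError):
            geolocate.position_from_twilight_pair(rise, sett, 96.0)

    @pytest.mark.parametrize("lat,lon", [(55.0, -10.0), (40.0, 20.0), (-35.0, 150.0)])
    def test_forward_inversion_round_trip(self, lat, lon):
        """Positions from forward-simulated twilights recover the truth to
        0.5 deg longitude / 1 deg latitude outside the equinox windows."""
        events = forward_twilights(lat, lon, 96.0, "2010-10-25", 30)
        fixes = geolocate.positions_from_twilights(events, 96.0)
        assert len(fixes) >= 28
        assert np.nanmax(np.abs(fixes["lon"] - lon)) < 0.5
        assert np.nanmax(np.abs(fixes["lat"] - lat)) < 1.0


class TestZenithCalibration:
    def test_recovers_true_zenith(self):
        events = forward_twilights(55.0, -10.0, 96.0, "2010-08-01", 120)
        cal = geolocate.calibrate_zenith(events)
        assert abs(cal.zenith - 96.0) <= 0.5

    def test_tie_goes_to_smaller_zenith(self):
        events = forward_twilights(55.0, -10.0, 96.0, "2010-08-01", 120)
        cal = geolocate.calibrate_zenith(events)
        obj = cal.objective
        tied = obj[np.isclose(obj.to_numpy(), obj.min())]
        assert cal.zenith == tied.index.min()

    def test_too_few_pairs_errors(self):
        events = forward_twilights(55.0, -10.0, 96.0, "2010-08-01", 10)
        with pytest.raises(geolocate.CalibrationError):
            geolocate.calibrate_zenith(events)

    def test_pure_noise_twilights_fail_calibration(self):
        rng = np.random.default_rng(0)
        ev = []
        for d in pd.date_range("2010-08-01", periods=90, freq="D"):
            # random 1-2 h "days": no zenith in range can explain them
            r = d + pd.Timedelta(hours=float(rng.uniform(0, 11)))
            s = r + pd.Timedelta(hours=float(rng.uniform(0.2, 2.0)))
            ev += [TwilightEvent(r, "rise"), TwilightEvent(s, "set")]
        with pytest.raises(geolocate.CalibrationError):
            geolocate.calibrate_zenith(ev)


class TestSmoothLatitudes:
    @staticmethod
    def _fixes(start, n, lat=55.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        dates = pd.date_range(start, periods=n, freq="D")
        return pd.DataFrame({"date": dates, "lon": -10.0,
                             "lat": lat + noise * rng.standard_normal(n),
                             "lat_quality": "raw"})

    def test_outside_windows_unchanged(self):
        fixes = self._fixes("2010-11-15", 30)
        out = geolocate.smooth_latitudes(fixes)
        np.testing.assert_array_equal(out["lat"], fixes["lat"])
        assert (out["lat_quality"] == "raw").all()

    def test_core_equinox_dates_interpolated(self):
        fixes = self._fixes("2010-08-22", 62)
        out = geolocate.smooth_latitudes(fixes).set_index("date")
        assert out.loc["2010-09-15", "lat_quality"] == "interpolated"
        assert out.loc["2010-08-25", "lat_quality"] == "loess_smoothed"

    def test_noisy_constant_latitude_recovered(self):
        fixes = self._fixes("2010-08-22", 62, noise=3.0)
        out = geolocate.smooth_latitudes(fixes)
        sm = out[out["lat_quality"] != "raw"]
        assert np.abs(sm["lat"] - 55.0).mean() < 3.0 / np.sqrt(10)

    def test_longitudes_untouched(self):
        fixes = self._fixes("2010-08-22", 62, noise=3.0)
        out = geolocate.smooth_latitudes(fixes)
        np.testing.assert_array_equal(out["lon"], fixes["lon"])


class TestSegmentation:
    @staticmethod
    def _distance_fixes(dists, colony=(51.737, -5.297), seed=0, sd=50.0):
        """Daily fixes due south of the colony at the given colony distances."""
        rng = np.random.default_rng(seed)
        dists = np.asarray(dists, dtype=float) + sd * rng.standard_normal(len(dists))
        lats = colony[0] - dists / 111.2
        dates = pd.date_range("2010-09-01", periods=len(dists), freq="D")
        return pd.DataFrame({"date": dates, "lon": colony[1], "lat": lats,
                             "lat_quality": "raw"})

    def test_two_level_series_changepoint_within_2_days(self):
        truth_cp = 40
        fixes = self._distance_fixes([800.0] * truth_cp + [2500.0] * 40)
        segs = geolocate.segment_residencies(fixes, (51.737, -5.297))
        assert len(segs) == 2
        cp = (segs[1].start - fixes["date"].iloc[0]).days
        assert abs(cp - truth_cp) <= 2
        assert abs(segs[0].mean_colony_distance_km - 800) < 100
        assert abs(segs[1].mean_colony_distance_km - 2500) < 100

    def test_constant_series_single_segment(self):
        fixes = self._distance_fixes([800.0] * 60)
        segs = geolocate.segment_residencies(fixes, (51.737, -5.297))
        assert len(segs) == 1

    def test_segments_contiguous_and_nonoverlapping(self):
        fixes = self._distance_fixes([500.0] * 30 + [1500.0] * 25 + [300.0] * 35)
        segs = geolocate.segment_residencies(fixes, (51.737, -5.297))
        for a, b in zip(segs[:-1], segs[1:]):
            assert b.start == a.end + pd.Timedelta(days=1)
        assert segs[0].start == fixes["date"].iloc[0]
        assert segs[-1].end == fixes["date"].iloc[-1]

    def test_changepoints_stable_under_small_noise(self):
        base = [800.0] * 40 + [2500.0] * 40
        cps = []
        for seed in range(10):
            fixes = self._distance_fixes(base, seed=seed)
            segs = geolocate.segment_residencies(fixes, (51.737, -5.297))
            cps.append(tuple((s.start - fixes["date"].iloc[0]).days for s in segs[1:]))
        best = max(set(cps), key=cps.count)
        same = sum(all(abs(a - b) <= 2 for a, b in zip(c, best)) and len(c) == len(best)
                   for c in cps)
        assert same >= 9

    def test_too_few_fixes_errors(self):
        fixes = self._distance_fixes([800.0] * 10)
        with pytest.raises(ValueError):
            geolocate.segment_residencies(fixes, (51.737, -5.297))


class TestMigrationMetrics:
    def test_max_distance_segment_reported(self):
        fixes = TestSegmentation._distance_fixes([728.0] * 41 + [400.0] * 30, sd=10.0)
        segs = geolocate.segment_residencies(fixes, (51.737, -5.297))
        m = geolocate.migration_metrics(segs)
        assert m["max_distance_km"] == pytest.approx(728, abs=60)
        assert m["duration_days"] == pytest.approx(41, abs=3)

    def test_single_segment_is_itself(self):
        seg = geolocate.ResidencySegment(pd.Timestamp("2010-09-01"), pd.Timestamp("2010-09-30"),
                                         -10.0, 50.0, 1234.0)
        m = geolocate.migration_metrics([seg])
        assert m["max_distance_km"] == 1234.0 and m["duration_days"] == 30


def test_haversine_known_distance():
    # London to Paris is ~344 km
    assert geolocate.haversine_km(51.5074, -0.1278, 48.8566, 2.3522) == pytest.approx(344, abs=5)
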