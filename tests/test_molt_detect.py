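import numpy as np
import pandas as pd
import pytest

from tuckmolt import molt_detect
from tuckmolt.molt_detect import daily_flight_proportion, detect_molts, find_molt_window, rolling_mean5

from conftest import make_immersion_series
from molt_oracle import oracle_find_molt, random_activity_series


def days_frame(pf5, start="2010-09-01"):
    dates = pd.date_range(start, periods=len(pf5), freq="D")
    return pd.DataFrame({"date": dates, "prop_flight": pf5, "prop_flight5": pf5})


class TestDailyFlightProportion:
    def _run(self, wet_counts, elev):
        imm = make_immersion_series(wet_counts)
        return daily_flight_proportion(imm, np.asarray(elev))

    def test_all_daylight_wet_zero_flight(self):
        out = self._run([200] * 6, [10.0] * 6)
        assert out["prop_flight"].iloc[0] == 0.0

    def test_all_daylight_dry_full_flight(self):
        out = self._run([0] * 6, [10.0] * 6)
        assert out["prop_flight"].iloc[0] == 1.0

    def test_half_wet_half_flight(self):
        out = self._run([100] * 6, [10.0] * 6)
        assert out["prop_flight"].iloc[0] == pytest.approx(0.5)

    def test_nocturnal_dry_bins_excluded(self):
        # dry at night, wet in daylight: the -3 deg gate hides the night dryness
        out = self._run([0, 0, 0, 200, 200, 200], [-10, -10, -10, 5, 5, 5])
        assert out["prop_flight"].iloc[0] == 0.0
        assert out["n_daylight_fixes"].iloc[0] == 3

    def test_day_without_daylight_undefined(self):
        out = self._run([0] * 6, [-10.0] * 6)
        assert np.isnan(out["prop_flight"].iloc[0])
        assert out["n_daylight_fixes"].iloc[0] == 0

    def test_empty_input_empty_output(self):
        imm = make_immersion_series([])
        out = daily_flight_proportion(imm, np.array([]))
        assert len(out) == 0


class TestRollingMean5:
    def test_constant_series_unchanged(self):
        days = days_frame([0.04] * 10)
        out = rolling_mean5(days.drop(columns="prop_flight5"))
        np.testing.assert_allclose(out["prop_flight5"], 0.04)

    def test_centered_mean_arithmetic(self):
        days = days_frame([0, 0, 1, 0, 0])
        out = rolling_mean5(days.drop(columns="prop_flight5"))
        assert out["prop_flight5"].iloc[2] == pytest.approx(0.2)

    def test_missing_day_averaged_over_available(self):
        days = days_frame([0.1, 0.1, np.nan, 0.1, 0.1])
        out = rolling_mean5(days.drop(columns="prop_flight5"))
        assert out["prop_flight5"].iloc[2] == pytest.approx(0.1)

    def test_fewer_than_three_defined_undefined(self):
        days = days_frame([0.1, np.nan, np.nan, np.nan, 0.1])
        out = rolling_mean5(days.drop(columns="prop_flight5"))
        assert np.isnan(out["prop_flight5"].iloc[2])


class TestFindMoltWindow:
    def test_zero_spell_found_at_first_increment(self):
        pf5 = np.array([0.05] * 30 + [0.0] * 35 + [0.05] * 30)
        w = find_molt_window(days_frame(pf5))
        assert w.threshold_used == pytest.approx(0.0002)
        assert w.duration_days == 35
        assert w.start_date == pd.Timestamp("2010-10-01")

    def test_cap_rule_blocks_merely_low_flight(self):
        pf5 = np.full(120, 0.012)  # above the 1% cap everywhere
        assert find_molt_window(days_frame(pf5)) is None

    def test_29_day_spell_too_short(self):
        pf5 = np.array([0.05] * 30 + [0.0] * 29 + [0.05] * 30)
        assert find_molt_window(days_frame(pf5)) is None

    def test_longest_run_wins(self):
        pf5 = np.array([0.05] * 10 + [0.0] * 30 + [0.05] * 10 + [0.0] * 40 + [0.05] * 10)
        w = find_molt_window(days_frame(pf5))
        assert w.duration_days == 40
        ref = oracle_find_molt(pd.date_range("2010-09-01", periods=100, freq="D"), pf5)
        assert (w.start_date, w.end_date, w.threshold_used) == (ref[0], ref[1], pytest.approx(ref[2]))

    def test_window_extends_over_sub_cap_shoulder(self):
        # a 30-day zero core flanked by days below the 1% cap: the reported
        # window is the whole continuous sub-cap spell
        pf5 = np.array([0.05] * 20 + [0.004] * 5 + [0.0] * 30 + [0.004] * 5 + [0.05] * 20)
        w = find_molt_window(days_frame(pf5))
        assert w.duration_days == 40
        assert w.threshold_used == pytest.approx(0.0002)

    def test_too_few_days_returns_none(self, caplog):
        with caplog.at_level("WARNING"):
            assert find_molt_window(days_frame([0.0] * 20)) is None

    def test_excluded_range_not_bridged(self):
        pf5 = np.zeros(80)
        days = days_frame(pf5)
        w = find_molt_window(days, excluded=[(pd.Timestamp("2010-09-30"), pd.Timestamp("2010-10-02"))])
        # runs on either side of the exclusion: Sep 1-29 (29 d) and Oct 3-Nov 19 (48 d)
        assert w.start_date == pd.Timestamp("2010-10-03")
        assert w.duration_days == 48

    def test_long_undefined_gap_not_bridged(self):
        pf5 = np.zeros(80)
        pf5[25:29] = np.nan  # 4-day gap breaks runs
        w = find_molt_window(days_frame(pf5))
        assert w.start_date == pd.Timestamp("2010-09-30")

    def test_two_day_gap_bridged(self):
        pf5 = np.concatenate([np.zeros(20), [np.nan, np.nan], np.zeros(20), np.full(40, 0.05)])
        w = find_molt_window(days_frame(pf5))
        assert w.duration_days == 42

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        dates = pd.date_range("2010-08-01", periods=150, freq="D")
        for _ in range(20):
            pf5, excl_idx = random_activity_series(rng, 150)
            excl = [(dates[a], dates[b]) for a, b in excl_idx]
            got = find_molt_window(days_frame(pf5, start="2010-08-01"), excluded=excl)
            ref = oracle_find_molt(dates, pf5, excluded_ranges=excl)
            if ref is None:
                assert got is None
            else:
                assert got is not None
                assert (got.start_date, got.end_date) == (ref[0], ref[1])
                assert got.threshold_used == pytest.approx(ref[2])


class TestDetectMolts:
    def test_two_spells_found_in_two_iterations(self):
        pf5 = np.array([0.05] * 20 + [0.0] * 40 + [0.05] * 60 + [0.0] * 32 + [0.05] * 20)
        windows = detect_molts(days_frame(pf5))
        assert len(windows) == 2
        assert [w.iteration for w in windows] == [1, 2]
        assert windows[0].duration_days == 40 and windows[1].duration_days == 32
        assert windows[0].end_date < windows[1].start_date

    def test_chronological_order_even_when_second_is_earlier(self):
        pf5 = np.array([0.05] * 20 + [0.0] * 32 + [0.05] * 60 + [0.0] * 40 + [0.05] * 20)
        windows = detect_molts(days_frame(pf5))
        assert [w.iteration for w in windows] == [2, 1]
        assert windows[0].start_date < windows[1].start_date

    def test_single_spell_single_window(self):
        pf5 = np.array([0.05] * 40 + [0.0] * 35 + [0.05] * 40)
        windows = detect_molts(days_frame(pf5))
        assert len(windows) == 1

    def test_no_spell_empty(self):
        rng = np.random.default_rng(0)
        pf5 = 0.02 + 0.01 * rng.random(200)
        assert detect_molts(days_frame(pf5)) == []

    def test_windows_do_not_overlap(self):
        pf5 = np.array([0.0] * 120)
        windows = detect_molts(days_frame(pf5))
        if len(windows) == 2:
            assert windows[0].end_date < windows[1].start_date

    def test_detected_windows_satisfy_invariants(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pf5, _ = random_activity_series(rng, 200)
            days = days_frame(pf5)
            for w in detect_molts(days):
                assert w.duration_days >= 30
                assert 0 < w.threshold_used <= 0.01
                sel = days.set_index("date").loc[w.start_date:w.end_date, "prop_flight5"]
                assert (sel.dropna() < 0.01).all()
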