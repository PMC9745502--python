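import numpy as np
import pandas as pd
import pytest

from tuckmolt import geo_io, simulate


def make_light_series(values, start="2010-08-01", interval=5, leg="left"):
    idx = pd.date_range(start, periods=len(values), freq=f"{interval}min")
    return geo_io.LightSeries(logger_id="test", leg=leg,
                              data=pd.DataFrame({"light": np.asarray(values)}, index=idx),
                              fix_interval=interval)


def make_immersion_series(values, start="2010-08-01", interval=10, leg="left", scale_max=200):
    idx = pd.date_range(start, periods=len(values), freq=f"{interval}min")
    return geo_io.ImmersionSeries(logger_id="test", leg=leg,
                                  data=pd.DataFrame({"wet_count": np.asarray(values)}, index=idx),
                                  fix_interval=interval, scale_max=scale_max)


def square_wave_light(n_days=10, day_start_h=6, day_end_h=18, level=60, interval=5):
    """Idealised light series: 0 at night, ``level`` between the given hours."""
    idx = pd.date_range("2010-08-01", periods=n_days * 24 * 60 // interval,
                        freq=f"{interval}min")
    hours = idx.hour + idx.minute / 60
    values = np.where((hours >= day_start_h) & (hours < day_end_h), level, 0)
    return make_light_series(values, interval=interval)


@pytest.fixture(scope="session")
def sim_bird():
    """One simulated dual-equipped bird (default scenario, molt Sep 15 + 40 d)."""
    params = simulate.BehaviorParams(seed=1)
    trace = simulate.simulate_behavior(params)
    return {
        "params": params,
        "trace": trace,
        "truth": simulate.ground_truth(trace),
        "light": {leg: simulate.render_light(trace, 5, leg) for leg in ("left", "right")},
        "immersion": {leg: simulate.render_immersion(trace, leg) for leg in ("left", "right")},
    }
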