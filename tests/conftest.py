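import numpy as np
import pytest

import breathgate as bg
from breathgate.features import feature_names


@pytest.fixture
def constant_trace():
    """30 L/min for 1 s at 1 kHz: exactly 500 mL exhaled."""
    return bg.constant_flow_trace(30.0, 1.0, 1000.0)


@pytest.fixture
def default_breath():
    """Noiseless 500 mL synthetic exhalation at the default 100 Hz."""
    return bg.generate_breath(bg.BreathProfile())


@pytest.fixture(scope="session")
def cohort_features():
    """Default clean cohort (n=115) as (X, y) feature matrix and labels."""
    samples = bg.generate_cohort(n=115, seed=7, dead_fraction=0.0)
    responses = [bg.sensor_response(s) for s in samples]
    table = bg.feature_table(responses, [s.label for s in samples])
    return table[feature_names()].to_numpy(), table["label"].to_numpy()


@pytest.fixture(scope="session")
def contaminated_features():
    """Same cohort seed at whole-breath contamination (f = 0.3)."""
    samples = bg.generate_cohort(n=115, seed=7, dead_fraction=0.3)
    responses = [bg.sensor_response(s) for s in samples]
    table = bg.feature_table(responses, [s.label for s in samples])
    return table[feature_names()].to_numpy(), table["label"].to_numpy()


def fine_grid_cumvol(trace: bg.FlowTrace, refine: int = 100):
    """Brute-force cumulative volume on a `refine`-times finer grid (mL).

    Independent of the package's integrator: linearly interpolates the flow
    onto the fine grid and accumulates rectangle areas of the midpoint rule.
    """
    t = np.linspace(trace.time[0], trace.time[-1], (trace.time.size - 1) * refine + 1)
    f_ml_s = np.interp(t, trace.time, trace.flow) * 1000.0 / 60.0
    mid = 0.5 * (f_ml_s[1:] + f_ml_s[:-1])
    return t, np.concatenate(([0.0], np.cumsum(mid * np.diff(t))))
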