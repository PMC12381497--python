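import numpy as np
import pandas as pd
import pytest

from hiberlitter.trace_io import TemperatureTrace


@pytest.fixture
def make_trace():
    """Factory for traces with explicit temperature sequences."""

    def _make(temps, animal_id="A1", start="2021-10-19", period=135.0):
        return TemperatureTrace(
            animal_id=animal_id,
            start_time=pd.Timestamp(start),
            temperatures=np.asarray(temps, dtype=float),
            sampling_period=period,
        )

    return _make


@pytest.fixture
def winter_trace(make_trace):
    """37 °C euthermia with one 12-sample 12 °C bout (27 h at 135-min sampling)."""
    temps = [37.0] * 20 + [12.0] * 12 + [37.0] * 20
    return make_trace(temps)


def brute_force_bouts(temps, period_min=135.0, threshold=30.0, min_hours=24.0):
    """Independent maximal-run enumerator used as the detection oracle."""
    runs = []
    i, n = 0, len(temps)
    while i < n:
        t = temps[i]
        if np.isfinite(t) and t < threshold:
            j = i
            while j + 1 < n and np.isfinite(temps[j + 1]) and temps[j + 1] < threshold:
                j += 1
            if (j - i + 1) * period_min / 60.0 >= min_hours:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs
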