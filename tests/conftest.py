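import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from eflow.series import DailyFlowSeries

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_series(values, start="1999-10-01", gauge_id="G1", area=10.0):
    """Daily series from a value array, Feb 29 removed to keep 365-day years."""
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=int(len(values) * 1.01) + 2, freq="D")
    idx = idx[~((idx.month == 2) & (idx.day == 29))][: len(values)]
    return DailyFlowSeries(
        gauge_id=gauge_id,
        flows=pd.Series(values, index=idx),
        drainage_area_km2=area,
    )


@pytest.fixture
def constant_series():
    """16 water years of constant flow 5."""
    return make_series(np.full(16 * 365, 5.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
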