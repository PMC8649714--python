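import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from mobiphen.io_gps import GpsTrace
from mobiphen import synthetic as syn

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_trace(ts, lats, lons, pid="T") -> GpsTrace:
    return GpsTrace(pid, pd.DataFrame({"t": np.asarray(ts, float),
                                       "lat": np.asarray(lats, float),
                                       "lon": np.asarray(lons, float)}))


@pytest.fixture(scope="session")
def small_cohort():
    """4 participants x 5 days from the pre2020 regime, fixed seed."""
    regime = dataclasses.replace(syn.PRESETS["pre2020"], n_participants=4, n_days=5)
    return syn.simulate_cohort(regime, syn.CouplingConfig(), seed=7)


@pytest.fixture(scope="session")
def small_cohort_traces(small_cohort):
    return small_cohort.traces
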