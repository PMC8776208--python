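from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20220112)


@pytest.fixture
def ten_day_hrv():
    """Ten consecutive fully observed nights of lnRMSSD."""
    dates = [date(2020, 7, 1) + timedelta(days=i) for i in range(10)]
    return pd.Series(np.linspace(3.8, 4.2, 10), index=pd.DatetimeIndex(dates))


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared where only reading is needed."""
    from hrvstress.synthetic import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(seed=42))
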