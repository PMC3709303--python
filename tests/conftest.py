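import numpy as np
import pandas as pd
import pytest

from ozonewarn import HourlySeries, SimConfig, simulate_hourly, summarize

#: reference bivariate quadratic: next-day ozone (ug/m3) from today's mean
#: ozone X1 (ug/m3) and maximum temperature X2 (deg C)
REFERENCE_QUAD_COEFFS = (0.005, 0.487, -0.091, 2.524, -16.434, 209.977)


@pytest.fixture(scope="session")
def quad_coeffs():
    return REFERENCE_QUAD_COEFFS


@pytest.fixture(scope="session")
def noisefree_series() -> HourlySeries:
    """Noise-free generator output: photostationary identities hold exactly."""
    cfg = SimConfig(seed=42, n_days=60, obs_noise_sd=0.0, missing_fraction=0.0)
    return simulate_hourly(cfg)


@pytest.fixture(scope="session")
def default_series() -> HourlySeries:
    """Default (noisy) generator output, 120 days."""
    return simulate_hourly(SimConfig(seed=42, n_days=120))


@pytest.fixture(scope="session")
def default_daily(default_series) -> pd.DataFrame:
    return summarize(default_series)


def make_constant_day(o3=np.nan, no=np.nan, no2=np.nan, temp=np.nan,
                      date="2010-06-01", **extra) -> HourlySeries:
    """One calendar day with constant values (NaN for absent variables)."""
    idx = pd.date_range(date, periods=24, freq="h")
    frame = pd.DataFrame(
        {"o3": o3, "no": no, "no2": no2, "temp_c": temp, **extra}, index=idx
    )
    return HourlySeries(frame)
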