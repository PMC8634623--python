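import numpy as np
import pandas as pd
import pytest

import sealphen as sp


@pytest.fixture(scope="session")
def default_config():
    return sp.SimConfig(rng_seed=0)


@pytest.fixture(scope="session")
def sim_bundle(default_config):
    """One full synthetic dataset bundle at the default configuration."""
    return sp.simulate_all(default_config)


@pytest.fixture(scope="session")
def season_summary(sim_bundle):
    fits = sp.fit_all_years(sim_bundle["surveys"])
    return sp.summarize_seasons(fits)


def logistic_counts(A, m, s, days):
    """Noise-free cumulative counts from the three-parameter logistic."""
    days = np.asarray(days, dtype=float)
    return A / (1.0 + np.exp((m - days) / s))


@pytest.fixture
def noise_free_series():
    days = np.arange(50, 131, 2, dtype=float)
    y = logistic_counts(200.0, 90.0, 10.0, days)
    return pd.DataFrame({"year": 2000, "day": days, "cum_count": y})
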