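import numpy as np
import pytest

from ovforecast import RollingConfig, generate, load_preset, rolling_forecast
from ovforecast.synthetic import worked_example_fixture


def simulate_subset_arma(ar_terms, ma_terms, n, sigma=1.0, seed=0, burn=300):
    """Independent subset-ARMA simulator (test-side oracle).

    w_t = sum phi_k w_{t-k} + eps_t - sum theta_k eps_{t-k}, matching the
    sign convention phi(B) w = Theta(B) eps with phi(B) = 1 - sum phi_k B^k.
    """
    rng = np.random.default_rng(seed)
    total = n + burn
    eps = rng.normal(0.0, sigma, size=total)
    w = np.zeros(total)
    for t in range(total):
        val = eps[t]
        for lag, c in ar_terms.items():
            if t - lag >= 0:
                val += c * w[t - lag]
        for lag, c in ma_terms.items():
            if t - lag >= 0:
                val -= c * eps[t - lag]
        w[t] = val
    return w[burn:]


# coefficients of the published endocrinology fit (AR lag 1; MA lags 2,3,6,7)
EOV_AR = {1: -0.51364}
EOV_MA = {2: 0.45393, 3: 0.25916, 6: -0.14116, 7: 0.42807}


@pytest.fixture(scope="session")
def worked_example():
    return worked_example_fixture()


@pytest.fixture(scope="session")
def eov_series():
    return generate(load_preset("eov_like"))


@pytest.fixture(scope="session")
def eov_rolling(eov_series):
    """One full 43/8 rolling run on the endocrinology-like preset."""
    return rolling_forecast(eov_series, RollingConfig(train_weeks=43))
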