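import numpy as np
import pytest

from survscreen import SyntheticConfig, generate_cohort_pair


@pytest.fixture(scope="session")
def small_pair():
    """A small paired cohort with one strongly planted gene."""
    cfg = SyntheticConfig(n_samples_per_cohort=120, n_genes=40, n_planted=1,
                          planted_hr=4.0, censor_rate=0.2, seed=11)
    return cfg, generate_cohort_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def surv_sim(rng, n, log_hr=0.0, rate=0.05, censor_upper=40.0, p_high=0.5):
    """Exponential PH data with a binary covariate; returns (times, events, x)."""
    x = (rng.random(n) < p_high).astype(float)
    t = rng.exponential(1.0 / (rate * np.exp(log_hr * x)))
    c = rng.uniform(0, censor_upper, n)
    return np.minimum(t, c), (t <= c).astype(int), x
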