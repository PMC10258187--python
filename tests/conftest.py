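import numpy as np
import pytest

from survequiv import CensoredSample, fit_event_model
from survequiv.datasets import load_veteran
from survequiv.families import get_family


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def veteran():
    """(reference, test) arms of the VA lung-cancer trial."""
    return load_veteran()


def make_censored_weibull(theta, n, censor_rate, t_max, seed, group=1):
    """One arm of Weibull event times under exponential + administrative
    censoring — the workhorse synthetic sample."""
    rng = np.random.default_rng(seed)
    y = get_family("weibull").rvs(theta, n, rng)
    c = rng.exponential(1.0 / censor_rate, n) if censor_rate > 0 else np.full(n, np.inf)
    obs = np.minimum(np.minimum(y, c), t_max)
    delta = (y <= np.minimum(c, t_max)).astype(int)
    return CensoredSample(obs, delta, group=group, t_max=t_max)


@pytest.fixture(scope="session")
def ph_arms():
    """A frozen medium-size two-arm dataset from the proportional-hazards
    power configuration, with Weibull fits for both arms."""
    s1 = make_censored_weibull((1.5, 3.4), 400, 0.1, 9, seed=101, group=1)
    s2 = make_censored_weibull((1.5, 3.7), 400, 0.05, 9, seed=202, group=2)
    return s1, s2, fit_event_model(s1, "weibull"), fit_event_model(s2, "weibull")
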