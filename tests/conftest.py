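import numpy as np
import pytest

from psmcea.config import reference_config
from psmcea.model import CEModel
from psmcea.synthetic import generate_trial


@pytest.fixture(scope="session")
def ref_config():
    return reference_config()


@pytest.fixture(scope="session")
def trial(ref_config):
    return generate_trial(ref_config.arms, seed=12345)


@pytest.fixture(scope="session")
def model(ref_config, trial):
    return CEModel(ref_config, trial).fit()


@pytest.fixture(scope="session")
def base_case(model):
    return model.base_case()


def km_product_limit_oracle(times, events, grid):
    """Brute-force product-limit estimator, independent of the implementation.

    At each distinct event time t: S *= 1 - d(t)/n(t) with n(t) the number
    still under observation just before t (censored subjects at t remain in
    the risk set for events at t).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    event_times = np.unique(times[events == 1])
    out = []
    for g in np.asarray(grid, dtype=float):
        s = 1.0
        for t in event_times:
            if t <= g:
                n_risk = np.sum(times >= t)
                d = np.sum((times == t) & (events == 1))
                s *= 1.0 - d / n_risk
        out.append(s)
    return np.array(out)
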