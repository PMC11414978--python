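import numpy as np
import pytest

import pathsurv as ps


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small pathway-structured cohort with known truth (shared, read-only)."""
    expr, surv, sets, truth = ps.simulate_preset("tiny", seed=11)
    return expr, surv, sets, truth


@pytest.fixture(scope="session")
def survival_toy():
    """200-sample single-signal survival data for solver tests."""
    rng = np.random.default_rng(7)
    n, p = 200, 5
    X = rng.standard_normal((n, p))
    beta = np.array([0.8, -0.5, 0.0, 0.3, 0.0])
    t_event = -np.log(rng.uniform(size=n)) / np.exp(X @ beta)
    censor = rng.uniform(0, 2.5, size=n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return X, time, event


def make_survival(rng, n, signal=None, censor_scale=2.5):
    """Random right-censored survival data; ``signal`` is an optional
    linear predictor driving the hazard."""
    lp = np.zeros(n) if signal is None else signal
    t_event = -np.log(rng.uniform(size=n)) / np.exp(lp)
    censor = rng.uniform(0, censor_scale, size=n)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return time, event
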