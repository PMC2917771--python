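import numpy as np
import pandas as pd
import pytest

import seedsurv as ss


@pytest.fixture(scope="session")
def small_planted():
    """Reduced-probe planted-module matrix for fast seed-clustering tests.

    Sample size stays at the design's 150 (recovery power depends on it);
    only the probe count is scaled down for speed.
    """
    m, truth = ss.gen_expression(
        n_probes=300, n_samples=150, module_size=30, inverse_size=8, rng_seed=42
    )
    return m, truth


@pytest.fixture(scope="session")
def cohort():
    """Full synthetic cohort at reduced probe count (survival/assoc tests)."""
    return ss.gen_cohort(ss.SimConfig(rng_seed=7, n_probes=300, module_size=30, inverse_size=8))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def exp_ph_cohort(n, beta, rng, censor_rate=0.3):
    """Two-group exponential proportional-hazards data: binary covariate x,
    hazard 0.1*exp(beta*x), uniform censoring. Returns (x, time, event)."""
    x = (rng.uniform(size=n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    if censor_rate > 0:
        c = rng.uniform(0, np.quantile(t, 0.9) * 2.5, size=n)
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    else:
        event = np.ones(n, dtype=int)
    return x, t, event
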