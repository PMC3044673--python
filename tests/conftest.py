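import numpy as np
import pytest

from bimodalgene import CriteriaConfig, SimulationConfig, generate_dataset

#: reduced mixture grid budget used throughout the unit tests to keep the
#: suite fast; the full default (200,000) only changes the initial grid
#: resolution, not the polished optimum (asserted by the oracle tests).
FAST_BUDGET = 20_000


@pytest.fixture(scope="session")
def fast_config():
    return CriteriaConfig(mixture_budget=FAST_BUDGET)


@pytest.fixture(scope="session")
def small_study():
    """One deterministic synthetic study shared by read-only tests."""
    cfg = SimulationConfig(n_genes=60, frac_bimodal=0.1,
                           frac_batch_affected=0.1, seed=5)
    return cfg, generate_dataset(cfg)


def mixture_draw(rng, n, p1, sep, s1=1.0, s2=1.0, mu=8.0):
    """Sample a two-component Gaussian with the given within-SD separation."""
    pooled = np.sqrt(p1 * s1**2 + (1 - p1) * s2**2)
    delta = sep * pooled
    low = rng.random(n) < p1
    return np.where(low, rng.normal(mu, s1, n), rng.normal(mu + delta, s2, n)), low
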