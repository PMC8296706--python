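import logging

import numpy as np
import pytest

from sigtrend import FitConfig, cohort_like_spec, fit, null_dataset, simulate_dataset

logging.getLogger("sigtrend").setLevel(logging.WARNING)


def rng(seed=0):
    return np.random.default_rng(seed)


@pytest.fixture(scope="session")
def signal_data():
    """Cohort-shaped dataset: 200 genes, 13 samples, 20 signal genes |beta1| in [1, 2]."""
    return simulate_dataset(cohort_like_spec(n_genes=200, seed=11, prop_de=0.1))


@pytest.fixture(scope="session")
def signal_fit(signal_data):
    """Posterior fit of the signal dataset (shared across recovery tests)."""
    cfg = FitConfig(seed=5, chains=2, warmup_draws=500, sampling_draws=500)
    return fit(signal_data.counts, signal_data.design, cfg)


@pytest.fixture(scope="session")
def null_data():
    """Null dataset (every slope of interest zero): 100 genes, 13 samples."""
    return null_dataset(cohort_like_spec(n_genes=100, seed=21))


@pytest.fixture(scope="session")
def null_fit(null_data):
    cfg = FitConfig(seed=9, chains=2, warmup_draws=500, sampling_draws=500)
    return fit(null_data.counts, null_data.design, cfg)


@pytest.fixture(scope="session")
def tiny_fit_pair():
    """A 5-gene strong-signal dataset fitted twice with the same seed."""
    spec = cohort_like_spec(n_genes=5, seed=3, prop_de=0.4, effect_range=(1.5, 2.0))
    data = simulate_dataset(spec)
    cfg = FitConfig(seed=17, chains=2, warmup_draws=300, sampling_draws=300)
    return data, fit(data.counts, data.design, cfg), fit(data.counts, data.design, cfg)
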