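import numpy as np
import pytest
from hypothesis import settings

from ogdex import hierarchical_model as hm
from ogdex import synthetic_data as sd

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_world() -> sd.GeneratorConfig:
    """A small stated world shared across model-level tests."""
    return sd.GeneratorConfig(n_plots=250, seed=11)


@pytest.fixture(scope="session")
def small_samples(small_world):
    return sd.gen_plot_samples(small_world)


@pytest.fixture(scope="session")
def small_fit(small_samples):
    """One fitted model reused by prediction/validation tests (reduced
    chain length keeps the suite fast; convergence is still reached)."""
    config = hm.FitConfig(burn_in=300, iterations=1500, seed=7,
                          max_extension_rounds=1)
    return hm.fit(small_samples, "I_og", config)
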