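import logging

import numpy as np
import pytest

from sizespectra.bootstrap import run_bootstrap
from sizespectra.catalog import load_base_catalog
from sizespectra.gev import FitConfig, fit_quantiles

logging.getLogger("sizespectra").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def base_catalog():
    return load_base_catalog()


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig()


@pytest.fixture(scope="session")
def base_initial_fits(base_catalog, fit_config):
    return {
        g.name: fit_quantiles(g.log_min, g.log_median, g.log_max, fit_config)
        for g in base_catalog
    }


@pytest.fixture(scope="session")
def small_ensemble(base_catalog, fit_config):
    """A light 20-replicate bootstrap of the base catalog."""
    return run_bootstrap(base_catalog, fit_config, n_boot=20, seed=7)


@pytest.fixture(scope="session")
def base_run_1000():
    """The full base analysis (1000 bootstraps) shared by the
    acceptance checks; seeded once for the whole session."""
    from sizespectra.pipeline import RunConfig, run_pipeline

    return run_pipeline(RunConfig(n_boot=1000, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
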