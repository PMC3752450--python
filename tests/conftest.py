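import numpy as np
import pytest

from nasotrans import default_baths, load_params, reference_state
from nasotrans.population import FilterBounds, run_filter


@pytest.fixture(scope="session")
def baths():
    return default_baths()


@pytest.fixture(scope="session")
def init_state(baths):
    return reference_state(baths)


@pytest.fixture(scope="session")
def params_nonCF():
    return load_params("table1_nonCF")


@pytest.fixture(scope="session")
def params_CF():
    return load_params("table1_CF")


@pytest.fixture(scope="session")
def params_baseline():
    return load_params("table1_baseline")


@pytest.fixture(scope="session")
def bounds_nonCF():
    return FilterBounds.from_condition("nonCF")


@pytest.fixture(scope="session")
def bounds_CF():
    return FilterBounds.from_condition("CF")


@pytest.fixture(scope="session")
def filtered_population(params_baseline):
    """One shared Monte Carlo filtering run, reused by the population,
    sensitivity, knockout and acceptance tests to keep the suite fast.
    10^5 draws yield on the order of a hundred accepted non-CF sets."""
    return run_filter(100_000, params_baseline, seed=20260928, variant="default")
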