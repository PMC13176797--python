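import warnings

import pytest

import warfce


@pytest.fixture(scope="session")
def params():
    """Default parameter set (the packaged configuration); the two
    documented range inconsistencies warn at load."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return warfce.load_parameters()


@pytest.fixture(scope="session")
def life_table():
    return warfce.default_life_table()


@pytest.fixture(scope="session")
def base_results(params, life_table):
    """Deterministic base-case results for the three strategies."""
    return warfce.base_case(params, life_table)


@pytest.fixture(scope="session")
def base_traces(params, life_table):
    return {s: warfce.run_cohort(params, life_table, s)
            for s in warfce.Strategy}
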