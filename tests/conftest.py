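import numpy as np
import pytest

from heatvuln import (
    IndicatorSchema,
    IndicatorTable,
    SyntheticConfig,
    VARIABLES,
    generate,
    load_fixture_correlation,
)


@pytest.fixture(scope="session")
def urban_corr():
    return load_fixture_correlation("urban")


@pytest.fixture(scope="session")
def rural_corr():
    return load_fixture_correlation("rural")


@pytest.fixture
def schema():
    return IndicatorSchema(stratum="urban")


@pytest.fixture
def make_table(schema):
    """Factory for small indicator tables from an (n, 10) array."""

    def _make(values, county_ids=None, area_ids=None):
        values = np.asarray(values, dtype=float)
        if county_ids is None:
            county_ids = [f"c{i}" for i in range(values.shape[0])]
        return IndicatorTable(county_ids, values, schema, area_ids)

    return _make


@pytest.fixture
def random_table(make_table):
    """Moderately sized random percentage table with no constant column."""
    rng = np.random.default_rng(42)
    return make_table(rng.uniform(1.0, 60.0, size=(30, len(VARIABLES))))


@pytest.fixture
def synthetic_table():
    """Default urban-preset synthetic table with its true latent scores."""
    return generate(SyntheticConfig(seed=7))
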