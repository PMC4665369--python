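import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_rows():
    from mthia.fixtures import load_fixture

    return load_fixture()


@pytest.fixture(scope="session")
def gene_mapper(fixture_rows):
    from mthia.fixtures import fixture_mapper

    return fixture_mapper(fixture_rows)


@pytest.fixture(scope="session")
def wc_duplex():
    from mthia.synthetic_data import DuplexSpec, gen_duplex

    return gen_duplex(DuplexSpec(sequence="GGCAUGCC"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
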