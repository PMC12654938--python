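import pytest

from screeneval import default_scheme, reference_tables
from screeneval.synthetic import GeneratorConfig, generate_matrix


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def ref():
    """Published weight vectors and score/rank tables of the 16-hospital panel."""
    return reference_tables()


@pytest.fixture()
def synthetic_matrix():
    """A reproducible 16 x 11 awarded-points matrix."""
    return generate_matrix(GeneratorConfig(seed=7))
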