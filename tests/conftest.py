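import pytest

from mechrag.fixtures import (
    FixtureConfig,
    HashEmbedder,
    MockTrapiTransport,
    generate_mini_drugmechdb,
)
from mechrag.paths import parse_drugmechdb


@pytest.fixture(scope="session")
def mini_db():
    """A small planted path database shared across tests: (document, truth)."""
    config = FixtureConfig(
        seed=1, n_paths=24, eligible_gene=4, eligible_metabolite=3,
        eligible_drug=4, n_duplicate_groups=1,
    )
    return generate_mini_drugmechdb(config)


@pytest.fixture(scope="session")
def mini_paths(mini_db):
    document, _ = mini_db
    return parse_drugmechdb(document)


@pytest.fixture(scope="session")
def mini_truth(mini_db):
    _, truth = mini_db
    return truth


@pytest.fixture(scope="session")
def resolver(mini_truth):
    return mini_truth.resolver()


@pytest.fixture()
def transport(mini_truth):
    return MockTrapiTransport.from_truth(mini_truth)


@pytest.fixture(scope="session")
def embedder():
    return HashEmbedder(dimension=64, seed=7)
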