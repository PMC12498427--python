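import pytest

from glycomine.knowledge_base import load_knowledge_base
from glycomine.monomer_selection import ModelParams
from glycomine.synthetic_fixtures import FixtureSpec, make_toy_kb


@pytest.fixture(scope="session")
def real_kb():
    """The packaged production knowledge base."""
    return load_knowledge_base()


@pytest.fixture(scope="session")
def toy_spec():
    return FixtureSpec(seed=7, implant_classes=("gcT1", "gcT2"), implant_positions=(50_000, 55_000))


@pytest.fixture(scope="session")
def toy_kb(tmp_path_factory, toy_spec):
    """Small (G=6, K=2) knowledge base written through the catalog loaders."""
    return make_toy_kb(tmp_path_factory.mktemp("toy_kb"), toy_spec)


@pytest.fixture(scope="session")
def params():
    return ModelParams(alpha=0.9, beta=0.05, gamma=0.3)
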