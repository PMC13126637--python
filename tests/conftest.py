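import pytest

from molevolve import (
    FixtureSpec,
    MoleculeRecord,
    build_library,
    generate_fixture_corpus,
)


@pytest.fixture(scope="session")
def corpus100():
    return generate_fixture_corpus(FixtureSpec(n_molecules=100, seed=11))


@pytest.fixture(scope="session")
def records100(corpus100):
    return [MoleculeRecord.from_smiles(s) for s in corpus100]


@pytest.fixture(scope="session")
def library(corpus100):
    return build_library(corpus100, max_heavy_atoms=10, top_fraction=0.05)
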