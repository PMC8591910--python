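import numpy as np
import pytest
from rdkit import Chem

from smifrag.fixtures import FixtureSpec, make_fixture, write_fixture
from smifrag.fragment import FragmentationConfig, fragment_file


@pytest.fixture(scope="session")
def fixture_corpus():
    """100 molecules across all six families (the standard test corpus)."""
    return make_fixture(FixtureSpec(n_molecules=100, rng_seed=7))


@pytest.fixture(scope="session")
def corpus_file(fixture_corpus, tmp_path_factory):
    path = tmp_path_factory.mktemp("corpus") / "train.smi"
    with open(path, "w") as fh:
        for smi, name in fixture_corpus:
            fh.write(f"{smi}\t{name}\n")
    return path


@pytest.fixture(scope="session")
def fragments_file(corpus_file, tmp_path_factory):
    path = tmp_path_factory.mktemp("frags") / "fragments.smi"
    fragment_file(corpus_file, path, FragmentationConfig(rng_seed=1))
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def canon(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, f"invalid SMILES {smiles!r}"
    return Chem.MolToSmiles(mol)
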