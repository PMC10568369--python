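import pytest

from surfkit.atomtypes import assign_types, element_fallback_def
from surfkit.energy import default_matrix
from surfkit.fixtures import make_toy_complex, make_two_atom_fixture, toy_def


@pytest.fixture(scope="session")
def toy_table():
    return toy_def()


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(seed=1)


@pytest.fixture(scope="session")
def toy_dimer():
    """Two-chain dimer without the ligand."""
    return make_toy_complex(seed=1, with_ligand=False)


@pytest.fixture(scope="session")
def matrix():
    return default_matrix()


@pytest.fixture(scope="session")
def two_carbons_typed():
    """The closed-form benchmark: two carbons 4 Å apart, expanded radius 3.1 Å."""
    s = make_two_atom_fixture(("C", "C"), 4.0)
    return assign_types(s, element_fallback_def(s))
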