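import pytest

from aacomp import Alphabet, Residue, default_alphabet


@pytest.fixture(scope="session")
def default_alpha():
    return default_alphabet()


@pytest.fixture
def gv_alphabet():
    """Two-residue synthetic alphabet (glycine/valine masses)."""
    return Alphabet([Residue("G", 57_021_464), Residue("V", 99_068_414)])


@pytest.fixture
def abc_alphabet():
    """Three-residue synthetic alphabet with small round masses."""
    return Alphabet([Residue("a", 3_000_000), Residue("b", 5_000_000),
                     Residue("c", 11_000_000)])
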