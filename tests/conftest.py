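import pytest
from hypothesis import settings

from tanglefold import FactorList, T, U, parse_invariant

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")


@pytest.fixture
def trna_tangle():
    """Tangle of the modified E. coli tRNA shape (five stems, one pseudoknot)."""
    return parse_invariant("1:1',2:4,3:5',5:4',2':3'")


@pytest.fixture
def trna_word():
    return FactorList(5, (T(3), T(4), U(2)))


@pytest.fixture
def big_hook_tangle():
    """Worked big-hook example: one upper hook, one size-5 lower hook, 4 crossings."""
    return parse_invariant("1:2,4:1',3:3',7:4',6:5',5:6',2':7'")


@pytest.fixture
def big_hook_word():
    return FactorList(7, (T(3), T(5), T(6), T(5), U(1), U(2), T(3), T(4), T(5), T(6)))


def word(n, *symbols):
    """Shorthand: word(5, "T3", "U2") -> FactorList."""
    return FactorList.from_string("*".join(symbols), n)
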