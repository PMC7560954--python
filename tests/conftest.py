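import pytest

from taboofree import Alphabet, TabooSet, catalog


@pytest.fixture
def dna_pairs():
    """Four two-letter taboos over ACGT: every repeated letter forbidden."""
    return TabooSet.from_strings({"AA", "CC", "GG", "TT"})


@pytest.fixture
def aa_ccc():
    """The small left proper set {AA, CCC} whose classification is all of suf(T)."""
    return TabooSet.from_strings({"AA", "CCC"})


@pytest.fixture
def binary_fib():
    """{11} over {0,1}: the Fibonacci-cube vertex sets."""
    return TabooSet(Alphabet.from_string("01"), frozenset({"11"}))


@pytest.fixture
def t_parva():
    return catalog.turneriella_parva()


@pytest.fixture
def h_pylori():
    return catalog.helicobacter_pylori()


@pytest.fixture
def b_imaginara():
    return catalog.bacterium_imaginara()
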