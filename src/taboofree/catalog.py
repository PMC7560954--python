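"""Named example taboo-sets used throughout the documentation and tests.

The bacterial examples are taboo-sets induced by published restriction-enzyme
recognition sites; the abstract examples are the small alphabets that
delimit what the sufficiency criteria can and cannot decide.
"""

from __future__ import annotations

from .biosites import expand_iupac, taboo_set_from_sites
from .core import DNA, Alphabet, TabooSet

__all__ = [
    "turneriella_parva",
    "helicobacter_pylori",
    "bacterium_imaginara",
    "binary_chain_breaker",
    "cut_vertex_example",
    "antichain_example",
    "isolated_suffix_example",
]


def turneriella_parva() -> TabooSet:
    """Two enzymes: ``GATC`` (an inverted repeat) and degenerate ``GGWCC``.

    Expansion with reverse complements yields the three taboos
    ``{GATC, GGACC, GGTCC}``: all start with ``G``, so the taboo-scarcity
    criterion immediately proves every suffix graph connected.
    """
    return taboo_set_from_sites(["GATC", "GGWCC"], add_revcomp=True)


def helicobacter_pylori() -> TabooSet:
    """The rich taboo-set of a heavily methylated strain: 28 taboos.

    Written by the first letter of each taboo: the ``A`` family is
    ``AC.N.GT``; the ``G`` family is ``GT.NN.AC`` plus ``GTCAC``, ``GTGAC``,
    ``GTAC`` and ``GAGG``; the ``C`` family is ``CCGG``, ``CCTC``, ``CATG``;
    and the single ``T`` taboo is ``TGCA``.  Six taboos have length four and
    22 have length five or more.
    """
    taboos: set[str] = set()
    taboos |= expand_iupac("ACNGT")
    taboos |= expand_iupac("GTNNAC")
    taboos |= {"GTCAC", "GTGAC", "GTAC", "GAGG"}
    taboos |= {"CCGG", "CCTC", "CATG"}
    taboos |= {"TGCA"}
    return TabooSet(DNA, frozenset(taboos))


def bacterium_imaginara() -> TabooSet:
    """A plausible four-enzyme taboo-set that disconnects a suffix graph.

    The sites ``ACCC``, ``TCCC``, ``CGCC`` and ``GGCC`` plus reverse
    complements give seven taboos (``GGCC`` is an inverted repeat).  The
    suffix graph of ``CCC`` splits for ``n >= 5`` into a ``GCCC``-suffixed
    and a ``CCCC``-suffixed component.
    """
    return taboo_set_from_sites(["ACCC", "TCCC", "CGCC", "GGCC"], add_revcomp=True)


def binary_chain_breaker() -> TabooSet:
    """``{11, 000}`` over ``{0, 1}``: the full graph disconnects at ``n = 3``
    (the vertex ``010`` becomes isolated)."""
    return TabooSet(Alphabet.from_string("01"), frozenset({"11", "000"}))


def cut_vertex_example(with_extra_taboo: bool = True) -> TabooSet:
    """Nine two-letter taboos leave ``TTT`` as a cut vertex of ``Gamma_3``.

    With ``with_extra_taboo`` the taboo ``TTT`` is added, removing the cut
    vertex and disconnecting ``Gamma_3``.
    """
    taboos = {"AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"}
    if with_extra_taboo:
        taboos.add("TTT")
    return TabooSet(DNA, frozenset(taboos))


def antichain_example() -> TabooSet:
    """``{10, 01}`` over ``{0, 1}``: only the constant strings survive, so
    ``Gamma_n`` is disconnected for ``n >= 2`` even though ``|T| = |Sigma|``."""
    return TabooSet(Alphabet.from_string("01"), frozenset({"10", "01"}))


def isolated_suffix_example(m: int = 3) -> TabooSet:
    """A tight family with ``|T| = |Sigma| = m`` and a disconnected suffix graph.

    Over ``{a_1, ..., a_m}`` (rendered as lowercase letters) the taboos are
    ``a_i a_1`` for ``i >= 3`` together with ``a_1 a_2`` and ``a_2 a_2``; the
    suffix graph of ``a_1`` is disconnected from ``n = 3`` on.
    """
    if m < 3:
        raise ValueError("the construction needs at least three symbols")
    import string as _string

    symbols = _string.ascii_lowercase[:m]
    a1, a2 = symbols[0], symbols[1]
    taboos = {symbols[i] + a1 for i in range(2, m)} | {a1 + a2, a2 + a2}
    return TabooSet(Alphabet.from_string(symbols), frozenset(taboos))
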