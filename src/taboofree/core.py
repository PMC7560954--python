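"""Alphabets, taboo-sets and taboo-set algebra.

A *taboo* is a forbidden substring of length at least two -- biologically, a
restriction-enzyme recognition site whose presence is lethal to the carrier.
A *taboo-set* collects finitely many taboos over a fixed finite alphabet; a
string is *taboo-free* when it contains none of them as a contiguous
substring.  This module provides the basic containers plus the rewriting
operations (minimality test and minimization) that keep the taboo-free
string sets ``V_n`` invariant while simplifying the taboo-set itself.

Conventions
-----------
* Symbols are single characters; the symbol order of the alphabet fixes all
  lexicographic tie-breaking in the package.
* The empty string ``""`` (written ``e`` in documentation) is always
  taboo-free, and positions in documentation are 1-based closed intervals
  ``s[i, j]``.
* An empty taboo-set is legal everywhere and means "no constraints".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .errors import InvalidSymbolError, InvalidTabooError

__all__ = [
    "Alphabet",
    "TabooSet",
    "DNA",
    "is_taboo_free",
    "proper_suffixes",
    "psi_set",
    "is_minimal",
    "minimize",
    "read_taboo_file",
]


@dataclass(frozen=True)
class Alphabet:
    """An ordered finite set of single-character symbols.

    The order of ``symbols`` is significant: every set the package serializes
    is sorted with respect to it, so two alphabets with the same symbols in a
    different order are distinct objects.
    """

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise InvalidSymbolError("an alphabet needs at least two symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise InvalidSymbolError(f"alphabet symbols must be distinct: {self.symbols!r}")
        for a in self.symbols:
            if not (isinstance(a, str) and len(a) == 1):
                raise InvalidSymbolError(
                    f"symbols must be single characters, got {a!r}"
                )

    @classmethod
    def from_string(cls, symbols: str) -> "Alphabet":
        return cls(tuple(symbols))

    @property
    def m(self) -> int:
        """Number of symbols."""
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def validate(self, s: str) -> str:
        """Return ``s`` unchanged, raising if it uses a foreign symbol."""
        for ch in s:
            if ch not in self.symbols:
                raise InvalidSymbolError(
                    f"symbol {ch!r} of {s!r} is not in alphabet {''.join(self.symbols)!r}"
                )
        return s

    def sort_key(self, s: str):
        """Lexicographic sort key respecting the alphabet's symbol order."""
        index = {a: i for i, a in enumerate(self.symbols)}
        return tuple(index[ch] for ch in s)


#: The four-nucleotide DNA alphabet, the package's main biological use case.
DNA = Alphabet.from_string("ACGT")


@dataclass(frozen=True)
class TabooSet:
    """A finite set of forbidden substrings over a fixed alphabet.

    Attributes
    ----------
    alphabet:
        The symbol set all taboos and all queried strings live over.
    taboos:
        The forbidden substrings, each of length at least two.
    """

    alphabet: Alphabet
    taboos: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for t in self.taboos:
            if len(t) < 2:
                raise InvalidTabooError(f"taboo {t!r} is shorter than 2 symbols")
            self.alphabet.validate(t)

    @classmethod
    def from_strings(
        cls, taboos: Iterable[str], alphabet: Optional[Alphabet | str] = None
    ) -> "TabooSet":
        """Build a taboo-set, defaulting the alphabet to ``ACGT``."""
        if alphabet is None:
            alphabet = DNA
        elif isinstance(alphabet, str):
            alphabet = Alphabet.from_string(alphabet)
        return cls(alphabet, frozenset(taboos))

    @property
    def M(self) -> Optional[int]:
        """Length of the longest taboo; ``None`` for the empty taboo-set."""
        if not self.taboos:
            return None
        return max(len(t) for t in self.taboos)

    def sorted_taboos(self) -> list[str]:
        return sorted(self.taboos, key=self.alphabet.sort_key)

    def suffix_set(self) -> frozenset[str]:
        """``suf(T)``: all proper suffixes of the taboos, plus ``e``."""
        return frozenset(proper_suffixes(self.taboos))

    def __iter__(self):
        return iter(self.taboos)

    def __len__(self) -> int:
        return len(self.taboos)


def is_taboo_free(s: str, taboo_set: TabooSet) -> bool:
    """True iff no taboo occurs in ``s`` as a contiguous substring.

    The empty string is always taboo-free, as is everything under an empty
    taboo-set.
    """
    taboo_set.alphabet.validate(s)
    return not any(t in s for t in taboo_set.taboos)


def proper_suffixes(strings: Iterable[str]) -> set[str]:
    """All proper suffixes of the given strings, always including ``e``.

    ``suf(S) = union over s in S of { s[i, |s|] : 2 <= i <= |s| } + { e }``.
    """
    out: set[str] = {""}
    for s in strings:
        for i in range(1, len(s)):
            out.add(s[i:])
    return out


def psi_set(taboo_set: TabooSet) -> set[str]:
    """Each taboo with its first symbol deleted.

    This set indexes the cheap pairwise-synchronization sufficiency test for
    connectivity (see :func:`taboofree.connectivity.check_psi_pairs`).  Empty
    for the empty taboo-set.
    """
    return {t[1:] for t in taboo_set.taboos}


def _taboo_free_strings_upto(taboo_set: TabooSet, max_len: int) -> Iterable[str]:
    """Yield every taboo-free string of length 0..max_len (lexicographic per length)."""
    level = [""]
    yield ""
    lengths = sorted({len(t) for t in taboo_set.taboos})
    taboos = taboo_set.taboos
    for _ in range(max_len):
        nxt = []
        for s in level:
            for a in taboo_set.alphabet:
                cand = s + a
                # only the new suffix windows can introduce a taboo
                if any(cand[-L:] in taboos for L in lengths if L <= len(cand)):
                    continue
                nxt.append(cand)
                yield cand
        level = nxt


def is_minimal(taboo_set: TabooSet) -> bool:
    """Check minimality of a taboo-set.

    A taboo-set is minimal when (a) no taboo is a proper substring of another
    and (b) no taboo-free string ``s`` shorter than the longest taboo has its
    full one-symbol extension family ``(s . Sigma) + (Sigma . s)`` contained
    in the taboo-set.  Both conditions are checked by direct enumeration,
    which is exponential in the longest taboo length but cheap at the scale
    of real recognition-site collections.
    """
    if not taboo_set.taboos:
        raise InvalidTabooError("minimality is undefined for an empty taboo-set")
    taboos = taboo_set.taboos
    for t1 in taboos:
        for t2 in taboos:
            if t1 != t2 and t2 in t1:
                return False
    M = taboo_set.M
    assert M is not None
    for s in _taboo_free_strings_upto(taboo_set, M - 1):
        family = {s + a for a in taboo_set.alphabet} | {a + s for a in taboo_set.alphabet}
        if family <= taboos:
            return False
    return True


def minimize(taboo_set: TabooSet) -> TabooSet:
    """Rewrite a taboo-set into a minimal one with the same ``V_n`` for ``n >= M``.

    Repeats two reductions to a fixpoint: (i) delete any taboo that contains
    another taboo as a substring, then (ii) contract any complete family
    ``(s . Sigma) + (Sigma . s)`` contained in the set to the single shorter
    taboo ``s``.  Candidate family roots are processed in (length,
    lexicographic) order, so the output is deterministic.  A contraction that
    would produce a taboo shorter than two symbols is skipped with a warning,
    since single symbols are not taboos.
    """
    if not taboo_set.taboos:
        raise InvalidTabooError("cannot minimize an empty taboo-set")
    alphabet = taboo_set.alphabet
    current = set(taboo_set.taboos)
    while True:
        # (i) substring deletion
        redundant = {
            t1 for t1 in current if any(t2 != t1 and t2 in t1 for t2 in current)
        }
        current -= redundant
        # (ii) family contraction, deterministic root order
        work = TabooSet(alphabet, frozenset(current))
        M = work.M
        assert M is not None
        contracted = False
        roots = sorted(
            _taboo_free_strings_upto(work, M - 1),
            key=lambda s: (len(s), alphabet.sort_key(s)),
        )
        for s in roots:
            family = {s + a for a in alphabet} | {a + s for a in alphabet}
            if family <= current:
                if len(s) < 2:
                    warnings.warn(
                        f"family of {s!r} cannot be contracted: a taboo needs "
                        "length >= 2; leaving the family in place",
                        stacklevel=2,
                    )
                    continue
                current -= family
                current.add(s)
                contracted = True
                break  # restart: lengths may have changed
        if not redundant and not contracted:
            return TabooSet(alphabet, frozenset(current))


def read_taboo_file(path: str | Path) -> TabooSet:
    """Read a plain-text taboo-set: one taboo per line, ``#`` comments.

    The alphabet may be declared on the first non-comment line as
    ``alphabet: ACGT``; otherwise it defaults to ``{A, C, G, T}``.
    """
    alphabet: Optional[Alphabet] = None
    taboos: list[str] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if alphabet is None and line.lower().startswith("alphabet:"):
            alphabet = Alphabet.from_string(line.split(":", 1)[1].strip())
            continue
        taboos.append(line)
    return TabooSet.from_strings(taboos, alphabet)
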