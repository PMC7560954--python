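"""Taboo-free sequence spaces: enumeration, prefixability and synchronization.

The vertex set ``V_n(T)`` of the taboo-free Hamming graph collects all
length-``n`` strings avoiding every taboo; ``V_n^s(T)`` restricts to strings
ending in a fixed suffix ``s`` (a conserved sequence fragment).  Everything
here is built by left extension: ``V_{n+1}`` is obtained by prepending every
allowed symbol to each string of ``V_n``, which only requires re-checking the
prefix windows that the new symbol creates.

Key quantities
--------------
``L^k(s)``
    The *k-prefixes* of ``s``: all length-``k`` strings ``w`` with ``ws``
    taboo-free.  ``s`` is *k-prefixable* when ``L^k(s)`` is nonempty.
``R^k(s)``
    The mirror image on the right (*k-suffixes*).
``k_s``
    Length of the longest prefix of ``s`` that is a proper suffix of some
    taboo.  The prefix ``s[1, k_s]`` is the canonical representative of the
    isomorphism class of the suffix graph of ``s``.
left *k*-synchronized
    Two taboo-free strings sharing at least one common *k*-prefix.
left proper
    Every taboo-free string of length ``M`` (longest taboo length) is
    1-prefixable; the regularity condition under which the classification
    machinery of :mod:`taboofree.classification` is proven.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .core import TabooSet, is_taboo_free
from .errors import EnumerationBudgetError, InvalidSymbolError, NotApplicableError

__all__ = [
    "DEFAULT_BUDGET",
    "SuffixClass",
    "enumerate_taboo_free",
    "prefix_extensions",
    "suffix_extensions",
    "longest_taboo_suffix_prefix",
    "is_left_proper",
    "is_right_proper",
    "is_suffix_viable",
    "are_left_k_synchronized",
]

#: Default cap on the number of candidate strings an enumeration may touch.
DEFAULT_BUDGET = 10_000_000


@dataclass(frozen=True)
class SuffixClass:
    """The canonical reduction of a taboo-free suffix.

    ``canonical = suffix[1, k]`` is the longest prefix of ``suffix`` lying in
    the proper-suffix set of the taboos; all suffix graphs of ``suffix`` are
    isomorphic to those of ``canonical`` (strip-suffix bijection).
    """

    suffix: str
    k: int
    canonical: str


def _check_suffix(taboo_set: TabooSet, suffix: str) -> None:
    if not is_taboo_free(suffix, taboo_set):
        raise InvalidSymbolError(f"suffix {suffix!r} is not taboo-free")


def enumerate_taboo_free(
    taboo_set: TabooSet,
    n: int,
    suffix: str = "",
    *,
    budget: int | None = DEFAULT_BUDGET,
) -> list[str]:
    """``V_n^suffix(T)`` in lexicographic (alphabet) order.

    Built by repeated left extension starting from ``suffix``.  When a step
    would touch more than ``budget`` candidate strings the enumeration
    refuses with :class:`EnumerationBudgetError`; pass ``budget=None`` to
    force it.
    """
    if n < len(suffix):
        raise ValueError(f"n={n} is shorter than the suffix {suffix!r}")
    _check_suffix(taboo_set, suffix)
    alphabet = taboo_set.alphabet
    taboos = taboo_set.taboos
    lengths = sorted({len(t) for t in taboos})
    level = [suffix]
    for _ in range(n - len(suffix)):
        if budget is not None and len(level) * alphabet.m > budget:
            raise EnumerationBudgetError(
                f"extension step would exceed the enumeration budget "
                f"({len(level)} x {alphabet.m} > {budget})"
            )
        nxt = []
        for s in level:
            for a in alphabet:
                cand = a + s
                # s is taboo-free, so only prefix windows need checking
                if any(cand[:L] in taboos for L in lengths if L <= len(cand)):
                    continue
                nxt.append(cand)
        level = nxt
    return sorted(level, key=alphabet.sort_key)


def prefix_extensions(taboo_set: TabooSet, s: str, k: int) -> set[str]:
    """``L^k(s)``: all ``w`` of length ``k`` with ``ws`` taboo-free."""
    if k < 0:
        raise ValueError("k must be non-negative")
    _check_suffix(taboo_set, s)
    return {v[:k] for v in enumerate_taboo_free(taboo_set, len(s) + k, s)}


def suffix_extensions(taboo_set: TabooSet, s: str, k: int) -> set[str]:
    """``R^k(s)``: all ``w`` of length ``k`` with ``sw`` taboo-free.

    Implemented by direct right extension; the string-reversal symmetry with
    :func:`prefix_extensions` is exercised in the test suite as an oracle.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if not is_taboo_free(s, taboo_set):
        raise InvalidSymbolError(f"string {s!r} is not taboo-free")
    taboos = taboo_set.taboos
    lengths = sorted({len(t) for t in taboos})
    level = [s]
    for _ in range(k):
        nxt = []
        for v in level:
            for a in taboo_set.alphabet:
                cand = v + a
                if any(cand[-L:] in taboos for L in lengths if L <= len(cand)):
                    continue
                nxt.append(cand)
        level = nxt
    return {v[len(s):] for v in level}


def longest_taboo_suffix_prefix(taboo_set: TabooSet, s: str) -> SuffixClass:
    """``k_s`` and the canonical prefix ``s[1, k_s]``.

    ``k_s`` is the largest ``i`` such that ``s[1, i]`` is a proper suffix of
    some taboo; it is well defined because ``e`` always qualifies, and is
    bounded by ``min(M - 1, |s|)``.
    """
    _check_suffix(taboo_set, s)
    suf = taboo_set.suffix_set()
    M = taboo_set.M
    hi = len(s) if M is None else min(M - 1, len(s))
    for i in range(hi, -1, -1):
        if s[:i] in suf:
            return SuffixClass(suffix=s, k=i, canonical=s[:i])
    raise AssertionError("unreachable: the empty prefix is always a taboo suffix")


@lru_cache(maxsize=None)
def is_left_proper(taboo_set: TabooSet) -> bool:
    """True iff every taboo-free string of length ``M`` is 1-prefixable.

    The empty taboo-set is trivially left proper.
    """
    M = taboo_set.M
    if M is None:
        return True
    for s in enumerate_taboo_free(taboo_set, M):
        if not prefix_extensions(taboo_set, s, 1):
            return False
    return True


@lru_cache(maxsize=None)
def is_right_proper(taboo_set: TabooSet) -> bool:
    """True iff every taboo-free string of length ``M`` is 1-suffixable."""
    M = taboo_set.M
    if M is None:
        return True
    for s in enumerate_taboo_free(taboo_set, M):
        if not suffix_extensions(taboo_set, s, 1):
            return False
    return True


def is_suffix_viable(taboo_set: TabooSet, s: str) -> bool:
    """Whether ``V_n^s(T)`` stays nonempty for all large ``n``.

    For a left proper taboo-set this holds iff ``|s| >= M`` or ``s`` is a
    proper suffix of some taboo-free string of length ``M``; the equivalence
    is only proven under left properness, so other taboo-sets are refused.
    """
    if not is_left_proper(taboo_set):
        raise NotApplicableError(
            "suffix viability is only characterized for left proper taboo-sets"
        )
    _check_suffix(taboo_set, s)
    M = taboo_set.M
    if M is None or len(s) >= M:
        return True
    from .core import proper_suffixes

    return s in proper_suffixes(enumerate_taboo_free(taboo_set, M))


def are_left_k_synchronized(taboo_set: TabooSet, s1: str, s2: str, k: int) -> bool:
    """True iff ``s1`` and ``s2`` share a common taboo-free left ``k``-extension.

    For ``k <= M - 1`` the intersection ``L^k(s1) & L^k(s2)`` is enumerated
    directly.  For larger ``k`` over a left proper taboo-set, two nonempty
    strings are ``k``-synchronized iff they are ``(M-1)``-synchronized, which
    bounds the enumeration; otherwise the intersection is enumerated as is.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    M = taboo_set.M
    if M is None:
        return True  # full Hamming space: Sigma^k is a common extension
    if k > M - 1 and s1 and s2 and is_left_proper(taboo_set):
        k = M - 1
    return bool(prefix_extensions(taboo_set, s1, k) & prefix_extensions(taboo_set, s2, k))
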