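"""Canonical suffix reduction and the long/short suffix classifications.

Every suffix graph ``Gamma_{n+|s|}^s(T)`` is isomorphic to the graph of the
canonical suffix ``s[1, k_s]`` (the longest prefix of ``s`` that is a proper
suffix of a taboo).  For a left proper taboo-set the canonical suffixes that
can actually occur form a finite set, split into:

``lsc(T)`` (long suffix classification)
    Canonical prefixes realized by some taboo-free string of length ``M``.
    Every suffix graph with ``|s| >= M`` reduces to one of these.
``ssc(T)`` (short suffix classification)
    The remaining members of ``suf(V_M(T)) & suf(T)``; only suffixes shorter
    than ``M`` can reduce to these.

These two sets index the finitely many graphs whose connectivity decides the
connectivity of *all* suffix graphs (see :mod:`taboofree.connectivity`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

from .core import TabooSet, is_minimal, proper_suffixes
from .errors import NotApplicableError
from .seqspace import (
    enumerate_taboo_free,
    is_left_proper,
    longest_taboo_suffix_prefix,
)

__all__ = ["ClassificationResult", "canonical_suffix", "compute_lsc", "compute_ssc"]


@dataclass(frozen=True)
class ClassificationResult:
    """The base set ``suf(V_M) & suf(T)`` split into ``lsc`` and ``ssc``."""

    lsc: frozenset[str]
    ssc: frozenset[str]
    base: frozenset[str]

    def to_dict(self) -> dict:
        return {
            "lsc": sorted(self.lsc, key=lambda s: (len(s), s)),
            "ssc": sorted(self.ssc, key=lambda s: (len(s), s)),
            "base": sorted(self.base, key=lambda s: (len(s), s)),
        }


def canonical_suffix(taboo_set: TabooSet, s: str) -> str:
    """``s[1, k_s]``: the canonical representative of ``s``'s suffix class."""
    return longest_taboo_suffix_prefix(taboo_set, s).canonical


def _require_left_proper(taboo_set: TabooSet) -> None:
    if not is_left_proper(taboo_set):
        raise NotApplicableError(
            "the suffix classification is only defined for left proper taboo-sets"
        )


@lru_cache(maxsize=None)
def compute_lsc(taboo_set: TabooSet) -> frozenset[str]:
    """The long suffix classification, by definitional scan over ``V_M(T)``.

    The scan is exponential in ``M``, which is fine at recognition-site
    scale; a warning (not an error) is emitted for non-minimal taboo-sets,
    whose redundant taboos inflate the scan for no gain.
    """
    _require_left_proper(taboo_set)
    M = taboo_set.M
    if M is None:
        raise NotApplicableError("the suffix classification needs a nonempty taboo-set")
    if not is_minimal(taboo_set):
        warnings.warn(
            "computing the suffix classification of a non-minimal taboo-set; "
            "minimize() it first for a cheaper scan",
            stacklevel=2,
        )
    return frozenset(
        longest_taboo_suffix_prefix(taboo_set, s).canonical
        for s in enumerate_taboo_free(taboo_set, M)
    )


@lru_cache(maxsize=None)
def compute_ssc(taboo_set: TabooSet) -> ClassificationResult:
    """Full classification: ``base = suf(V_M) & suf(T)``, ``ssc = base - lsc``."""
    lsc = compute_lsc(taboo_set)
    M = taboo_set.M
    assert M is not None
    base = frozenset(
        proper_suffixes(enumerate_taboo_free(taboo_set, M))
    ) & taboo_set.suffix_set()
    return ClassificationResult(lsc=lsc, ssc=frozenset(base - lsc), base=frozenset(base))
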