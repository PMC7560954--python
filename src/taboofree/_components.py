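"""Vectorized enumeration and component labeling for exhaustive scans.

This is the workhorse behind the exhaustive connectivity oracle: it encodes
length-``n`` strings as base-``m`` integers (leftmost symbol most
significant, so numeric order is lexicographic order) and finds connected
components of Hamming-distance-1 graphs *without* materializing edges.

The trick: for a fixed position ``p``, all vertices that agree everywhere
except possibly at ``p`` share the same "wildcard key" (the code with digit
``p`` zeroed) and form a clique under single-position substitution.  Iterated
group-minimum label propagation over these cliques, restricted to the free
(non-suffix) positions, therefore converges to the connected components of
every suffix graph of a given suffix length simultaneously.
"""

from __future__ import annotations

import numpy as np

from .core import TabooSet
from .errors import EnumerationBudgetError

__all__ = ["encode", "decode", "taboo_free_codes", "suffix_component_labels", "disconnected_suffix_codes"]


def encode(s: str, alphabet) -> int:
    digit = {a: i for i, a in enumerate(alphabet.symbols)}
    code = 0
    for ch in s:
        code = code * alphabet.m + digit[ch]
    return code


def decode(code: int, length: int, alphabet) -> str:
    out = []
    for _ in range(length):
        code, d = divmod(code, alphabet.m)
        out.append(alphabet.symbols[d])
    return "".join(reversed(out))


def taboo_free_codes(
    taboo_set: TabooSet, n: int, *, budget: int | None = 10_000_000
) -> np.ndarray:
    """Sorted integer codes of ``V_n(T)``, built by left extension."""
    m = taboo_set.alphabet.m
    by_len: dict[int, np.ndarray] = {}
    for t in taboo_set.taboos:
        by_len.setdefault(len(t), []).append(encode(t, taboo_set.alphabet))  # type: ignore[arg-type]
    by_len = {L: np.sort(np.asarray(codes, dtype=np.int64)) for L, codes in by_len.items()}
    level = np.zeros(1, dtype=np.int64)
    for l in range(n):
        if budget is not None and level.size * m > budget:
            raise EnumerationBudgetError(
                f"extension step would exceed the enumeration budget "
                f"({level.size} x {m} > {budget})"
            )
        base = m**l
        cand = (
            np.arange(m, dtype=np.int64)[:, None] * base + level[None, :]
        ).ravel()
        keep = np.ones(cand.size, dtype=bool)
        for L, tcodes in by_len.items():
            if L <= l + 1:
                prefixes = cand // (m ** (l + 1 - L))
                keep &= ~np.isin(prefixes, tcodes)
        level = np.sort(cand[keep])
    return level


def suffix_component_labels(
    codes: np.ndarray, n: int, m: int, suffix_len: int
) -> np.ndarray:
    """Component labels for all suffix graphs of one suffix length at once.

    ``labels[i] == labels[j]`` iff vertices ``i`` and ``j`` lie in the same
    connected component of the Hamming graph restricted to their (identical)
    suffix of length ``suffix_len``.  Vertices with different suffixes are
    never merged because every union group fixes all suffix positions.
    """
    N = codes.size
    labels = np.arange(N, dtype=np.int64)
    if N == 0:
        return labels
    groups = []
    for p in range(n - suffix_len):  # 0-based position from the left
        power = np.int64(m) ** (n - 1 - p)
        digit = (codes // power) % m
        key = codes - digit * power
        order = np.argsort(key, kind="stable")
        sorted_key = key[order]
        starts = np.flatnonzero(np.r_[True, sorted_key[1:] != sorted_key[:-1]])
        sizes = np.diff(np.r_[starts, np.int64(sorted_key.size)])
        groups.append((order, starts, sizes))
    while True:
        changed = False
        for order, starts, sizes in groups:
            current = labels[order]
            group_min = np.minimum.reduceat(current, starts)
            spread = np.repeat(group_min, sizes)
            if (spread < current).any():
                changed = True
                labels[order] = spread
        for _ in range(3):  # pointer jumping accelerates convergence
            jumped = labels[labels]
            if np.array_equal(jumped, labels):
                break
            labels = jumped
        if not changed:
            return labels


def disconnected_suffix_codes(
    codes: np.ndarray, labels: np.ndarray, m: int, suffix_len: int
) -> np.ndarray:
    """Suffix codes (ascending, i.e. lexicographic) with more than one component."""
    if codes.size == 0:
        return np.empty(0, dtype=np.int64)
    suffix_key = codes % (np.int64(m) ** suffix_len)
    order = np.argsort(suffix_key, kind="stable")
    sk = suffix_key[order]
    lo = labels[order]
    starts = np.flatnonzero(np.r_[True, sk[1:] != sk[:-1]])
    mins = np.minimum.reduceat(lo, starts)
    maxs = np.maximum.reduceat(lo, starts)
    return sk[starts[mins != maxs]]
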