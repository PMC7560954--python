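"""Hamming graphs on taboo-free vertex sets and their quotient graphs.

The taboo-free Hamming graph ``Gamma_n^s(T)`` has vertex set ``V_n^s(T)``
(taboo-free strings of length ``n`` ending in ``s``) and an edge between two
strings iff their Hamming distance is one -- a single substitution.  Edges
are generated by mutating each free position to each other symbol and testing
membership, which is ``O(n * |Sigma| * |V|)`` rather than all-pairs.

The quotient graph collapses each block ``V_n^{ws}`` of the *k*-prefix
partition of ``V_n^s`` to a single vertex ``w``; two blocks are adjacent iff
``d(w1, w2) = 1`` and ``w1 s``, ``w2 s`` are left ``(n - |s| - k)``-
synchronized.  Blocks that are empty at length ``n`` are dropped, so the
result coincides with the graph-theoretic quotient of the explicit suffix
graph.
"""

from __future__ import annotations

import json

import networkx as nx

from .core import TabooSet
from .errors import InvalidSymbolError
from .seqspace import (
    DEFAULT_BUDGET,
    enumerate_taboo_free,
    longest_taboo_suffix_prefix,
)

__all__ = [
    "hamming_distance",
    "build_suffix_graph",
    "connected_components",
    "quotient_graph",
    "canonical_isomorphism",
    "edge_list_text",
    "node_link_json",
]


def hamming_distance(s1: str, s2: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(s1) != len(s2):
        raise InvalidSymbolError(
            f"Hamming distance needs equal lengths: {len(s1)} != {len(s2)}"
        )
    return sum(a != b for a, b in zip(s1, s2))


def build_suffix_graph(
    taboo_set: TabooSet,
    suffix: str,
    n: int,
    *,
    budget: int | None = DEFAULT_BUDGET,
) -> nx.Graph:
    """``Gamma_n^suffix(T)`` as a :class:`networkx.Graph`.

    All vertices share the fixed suffix, so only the leading ``n - |suffix|``
    positions are mutated when generating edges.
    """
    vertices = enumerate_taboo_free(taboo_set, n, suffix, budget=budget)
    graph = nx.Graph(n=n, suffix=suffix)
    graph.add_nodes_from(vertices)
    vset = set(vertices)
    symbols = taboo_set.alphabet.symbols
    free = n - len(suffix)
    for v in vertices:
        for pos in range(free):
            for a in symbols:
                if a == v[pos]:
                    continue
                u = v[:pos] + a + v[pos + 1:]
                if u > v and u in vset:  # emit each edge once
                    graph.add_edge(v, u)
    return graph


def connected_components(graph: nx.Graph) -> list[list[str]]:
    """Components as sorted vertex lists, ordered by their smallest vertex."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: c[0])


def quotient_graph(taboo_set: TabooSet, s: str, k: int, n: int) -> nx.Graph:
    """Quotient of ``Gamma_n^s(T)`` under the ``k``-prefix partition.

    Vertices are the prefixes ``w`` in ``L^k(s)`` whose block ``V_n^{ws}`` is
    nonempty; ``{w1, w2}`` is an edge iff ``d(w1, w2) = 1`` and the blocks
    are joined by at least one Hamming-graph edge, i.e. ``w1 s`` and
    ``w2 s`` share a left ``(n - |s| - k)``-extension.
    """
    if n < len(s) + k:
        raise ValueError("n must be at least |s| + k")
    ext_len = n - len(s) - k
    # one enumeration of V_n^s yields both the blocks and their extensions
    extensions: dict[str, set[str]] = {}
    for v in enumerate_taboo_free(taboo_set, n, s):
        w = v[ext_len:ext_len + k]
        extensions.setdefault(w, set()).add(v[:ext_len])
    graph = nx.Graph(s=s, k=k, n=n)
    index = sorted(extensions, key=taboo_set.alphabet.sort_key)
    graph.add_nodes_from(index)
    for i, w1 in enumerate(index):
        for w2 in index[i + 1:]:
            if hamming_distance(w1, w2) == 1 and extensions[w1] & extensions[w2]:
                graph.add_edge(w1, w2)
    return graph


def canonical_isomorphism(
    taboo_set: TabooSet, s: str, n: int
) -> tuple[dict[str, str], nx.Graph, nx.Graph]:
    """The strip-suffix bijection between a suffix graph and its canonical form.

    Returns ``(mapping, G, H)`` where ``G = Gamma_{n+|s|}^s(T)``,
    ``H = Gamma_{n+k_s}^{s[1, k_s]}(T)`` and ``mapping`` sends ``r s`` to
    ``r s[1, k_s]``.  The mapping is an explicit graph isomorphism (it
    preserves the mutable prefix ``r``, on which all edges live).
    """
    cls = longest_taboo_suffix_prefix(taboo_set, s)
    G = build_suffix_graph(taboo_set, s, n + len(s))
    H = build_suffix_graph(taboo_set, cls.canonical, n + cls.k)
    mapping = {v: v[:n] + cls.canonical for v in G.nodes}
    return mapping, G, H


def edge_list_text(graph: nx.Graph) -> str:
    """Tab-separated edge list, one edge per line, lexicographic order."""
    lines = [f"{min(u, v)}\t{max(u, v)}" for u, v in graph.edges]
    return "\n".join(sorted(lines)) + ("\n" if lines else "")


def node_link_json(graph: nx.Graph) -> str:
    """JSON node-link rendering for visualization tools."""
    data = nx.node_link_data(graph, edges="links")
    return json.dumps(data, sort_keys=True)
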