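"""The layered decision procedure for suffix-graph connectivity.

Given a taboo-set ``T``, the engine decides whether *every* suffix Hamming
graph ``Gamma_n^s(T)`` is connected, trying progressively more expensive
criteria:

1. **Taboo scarcity** (:func:`check_taboo_scarcity`): if the taboos use
   fewer distinct initial letters than the alphabet has symbols -- in
   particular if there are fewer taboos than symbols -- every suffix graph
   is connected.
2. **Psi pair synchronization** (:func:`check_psi_pairs`): delete the first
   symbol of every taboo to obtain ``Psi(T)``; if every pair of taboo-free
   members at Hamming distance <= 1 (after truncating the longer one) shares
   a common one-symbol left extension, every suffix graph is connected.
3. **Suffix classification** (:func:`check_suffix_classification`): for a
   left proper taboo-set, connectivity of all suffix graphs is *equivalent*
   to the connectivity of finitely many checkpoint graphs indexed by the
   long/short suffix classifications; a failed checkpoint yields a concrete
   disconnection witness.

For taboo-sets that are not left proper, only a bounded brute-force search
is attempted: any disconnection it finds is sound, but finding none leaves
the question undecided.

An exhaustive, vectorized scan (:func:`exhaustive_scan`) and an explicit
BFS-based search (:func:`brute_force_all_connected`) serve as independent
oracles for the theorem-based engine: they share no code path with it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from ._components import (
    decode,
    disconnected_suffix_codes,
    suffix_component_labels,
    taboo_free_codes,
)
from .classification import compute_ssc
from .core import TabooSet, is_taboo_free, psi_set
from .errors import NotApplicableError
from .graphs import (
    build_suffix_graph,
    connected_components,
    hamming_distance,
    quotient_graph,
)
from .seqspace import (
    are_left_k_synchronized,
    enumerate_taboo_free,
    is_left_proper,
)

__all__ = [
    "ALL_CONNECTED",
    "DISCONNECTED",
    "UNDECIDED",
    "Witness",
    "ConnectivityVerdict",
    "LengthMPairReport",
    "BruteForceReport",
    "check_taboo_scarcity",
    "check_psi_pairs",
    "check_length_m_pairs",
    "check_suffix_classification",
    "decide_connectivity",
    "first_disconnected_n",
    "brute_force_all_connected",
    "exhaustive_scan",
]

ALL_CONNECTED = "all_connected"
DISCONNECTED = "disconnected"
UNDECIDED = "undecided"


@dataclass(frozen=True)
class Witness:
    """A verified disconnection: two vertices of ``Gamma_n^suffix`` in distinct components."""

    suffix: str
    n: int
    component_a_rep: str
    component_b_rep: str

    def to_dict(self) -> dict:
        return {
            "suffix": self.suffix,
            "n": self.n,
            "component_a_rep": self.component_a_rep,
            "component_b_rep": self.component_b_rep,
        }


@dataclass(frozen=True)
class ConnectivityVerdict:
    """Outcome of the decision procedure.

    ``status`` is ``all_connected`` (proven by a sufficient criterion),
    ``disconnected`` (with at least one verified witness) or ``undecided``
    (only possible for non-left-proper taboo-sets whose bounded search found
    nothing).  ``rule`` names the deciding criterion; ``checked`` lists the
    ``(suffix, n)`` checkpoint graphs the classification route examined.
    """

    status: str
    rule: str
    left_proper: Optional[bool] = None
    witnesses: tuple[Witness, ...] = ()
    lsc: tuple[str, ...] = ()
    ssc: tuple[str, ...] = ()
    checked: tuple[tuple[str, int], ...] = ()
    notes: str = ""
    parameters: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "rule": self.rule,
            "left_proper": self.left_proper,
            "lsc": list(self.lsc),
            "ssc": list(self.ssc),
            "witnesses": [w.to_dict() for w in self.witnesses],
            "checked": [list(c) for c in self.checked],
            "notes": self.notes,
            "parameters": self.parameters,
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _is_connected(graph: nx.Graph) -> bool:
    """Connectivity with the convention that <= 1 vertex (incl. empty) is connected."""
    if graph.number_of_nodes() <= 1:
        return True
    return nx.is_connected(graph)


def check_taboo_scarcity(taboo_set: TabooSet) -> Optional[ConnectivityVerdict]:
    """Sufficiency by counting: few initial letters, or few taboos.

    If the set of first letters of the taboos is smaller than the alphabet,
    any two taboo-free strings can be prefixed by a common safe letter, so
    every suffix graph is connected.  Fewer taboos than symbols is a special
    case.  Returns ``None`` when neither bound applies; the bound is tight
    (``|T| = |Sigma|`` can already disconnect a suffix graph).
    """
    m = taboo_set.alphabet.m
    initials = {t[0] for t in taboo_set.taboos}
    if len(initials) < m:
        rule = "few_initial_letters" if taboo_set.taboos else "few_taboos"
        return ConnectivityVerdict(
            status=ALL_CONNECTED,
            rule=rule,
            notes=f"{len(initials)} distinct taboo initial letters < {m} alphabet symbols",
        )
    if len(taboo_set.taboos) < m:
        return ConnectivityVerdict(
            status=ALL_CONNECTED,
            rule="few_taboos",
            notes=f"{len(taboo_set.taboos)} taboos < {m} alphabet symbols",
        )
    return None


def check_psi_pairs(taboo_set: TabooSet) -> Optional[ConnectivityVerdict]:
    """Sufficiency by pairwise synchronization of first-symbol-deleted taboos.

    Builds ``Psi(T)`` (every taboo with its first symbol removed) and checks
    that every pair of taboo-free members ``w1, w2`` with ``|w1| >= |w2|``
    and ``d(w1[1, |w2|], w2) <= 1`` -- including each member paired with
    itself -- is left 1-synchronized.  If so, every taboo-free string is
    1-prefixable and every suffix graph is connected.
    """
    if not taboo_set.taboos:
        return None
    members = sorted(
        (w for w in psi_set(taboo_set) if is_taboo_free(w, taboo_set)),
        key=lambda w: (len(w), taboo_set.alphabet.sort_key(w)),
    )
    for i, w2 in enumerate(members):
        for w1 in members[i:]:  # |w1| >= |w2| by the sort
            if len(w1) < len(w2):
                continue
            if hamming_distance(w1[: len(w2)], w2) > 1:
                continue
            if not are_left_k_synchronized(taboo_set, w1, w2, 1):
                return None
    return ConnectivityVerdict(
        status=ALL_CONNECTED,
        rule="psi_pair_synchronization",
        left_proper=True,
        notes="every close pair of first-symbol-deleted taboos shares a left extension",
    )


@dataclass(frozen=True)
class LengthMPairReport:
    """Diagnostic: synchronization of distance-1 pairs of full-length strings.

    When every pair ``w1, w2`` in ``V_M(T)`` at Hamming distance 1 is left
    1-synchronized, all suffix graphs indexed by the long suffix
    classification are connected, and the remaining work reduces to the
    short-classification members whose graph ``Gamma^p_M`` is connected.
    This never yields a full verdict by itself (suffix graphs shorter than
    ``M`` are not covered), hence it is exposed as a diagnostic only.
    """

    condition_holds: bool
    failing_pair: Optional[tuple[str, str]]
    ssc_graph_connected: dict[str, bool]


def check_length_m_pairs(taboo_set: TabooSet) -> LengthMPairReport:
    if not is_left_proper(taboo_set):
        raise NotApplicableError(
            "the distance-1 pair test is only proven for left proper taboo-sets"
        )
    M = taboo_set.M
    if M is None:
        return LengthMPairReport(True, None, {})
    strings = enumerate_taboo_free(taboo_set, M)
    for i, w1 in enumerate(strings):
        for w2 in strings[i + 1:]:
            if hamming_distance(w1, w2) != 1:
                continue
            if not are_left_k_synchronized(taboo_set, w1, w2, 1):
                return LengthMPairReport(False, (w1, w2), {})
    ssc = compute_ssc(taboo_set).ssc
    settled = {
        p: _is_connected(build_suffix_graph(taboo_set, p, M))
        for p in sorted(ssc, key=lambda s: (len(s), s))
    }
    return LengthMPairReport(True, None, settled)


def first_disconnected_n(
    taboo_set: TabooSet, suffix: str, max_n: int
) -> Optional[int]:
    """Smallest ``n`` in ``[|suffix|, max_n]`` with ``Gamma_n^suffix`` disconnected."""
    for n in range(len(suffix), max_n + 1):
        if not _is_connected(build_suffix_graph(taboo_set, suffix, n)):
            return n
    return None


def _witness_for_suffix(taboo_set: TabooSet, suffix: str, max_n: int) -> Witness:
    """Witness at the smallest disconnected length for ``suffix`` (<= max_n)."""
    n = first_disconnected_n(taboo_set, suffix, max_n)
    if n is None:
        raise AssertionError(f"no disconnection below {max_n} for suffix {suffix!r}")
    comps = connected_components(build_suffix_graph(taboo_set, suffix, n))
    return Witness(
        suffix=suffix, n=n, component_a_rep=comps[0][0], component_b_rep=comps[1][0]
    )


def check_suffix_classification(taboo_set: TabooSet) -> ConnectivityVerdict:
    """The full characterization for left proper taboo-sets.

    Checks the quotient graph of ``Gamma^r_{M+|r|}`` over the one-symbol
    prefix partition for every ``r`` in the long suffix classification, the
    quotient graph of ``Gamma^p_{2M-1}`` over the ``(M-|p|)``-prefix
    partition for every ``p`` in the short one, and the small graphs
    ``Gamma^p_n`` for ``|p|+2 <= n <= M-1`` (a vacuous range when
    ``M <= 3``).  All connected is *equivalent* to every suffix graph being
    connected; the first failing checkpoint produces a witness at the
    smallest disconnected length for that suffix.
    """
    if not is_left_proper(taboo_set):
        raise NotApplicableError(
            "the suffix classification characterization needs a left proper taboo-set"
        )
    M = taboo_set.M
    if M is None:
        return ConnectivityVerdict(
            status=ALL_CONNECTED,
            rule="suffix_classification",
            left_proper=True,
            notes="empty taboo-set: full Hamming graphs are connected",
        )
    cls = compute_ssc(taboo_set)
    lsc = sorted(cls.lsc, key=lambda s: (len(s), taboo_set.alphabet.sort_key(s)))
    ssc = sorted(cls.ssc, key=lambda s: (len(s), taboo_set.alphabet.sort_key(s)))
    checked: list[tuple[str, int]] = []
    failing: dict[str, int] = {}  # suffix -> bound on the failing length

    for r in lsc:
        n = M + len(r)
        checked.append((r, n))
        if not _is_connected(quotient_graph(taboo_set, r, 1, n)):
            failing.setdefault(r, n)
    for p in ssc:
        n = 2 * M - 1
        checked.append((p, n))
        if not _is_connected(quotient_graph(taboo_set, p, M - len(p), n)):
            failing.setdefault(p, n)
        for small_n in range(len(p) + 2, M):  # vacuous when M <= 3
            checked.append((p, small_n))
            if not _is_connected(build_suffix_graph(taboo_set, p, small_n)):
                failing.setdefault(p, small_n)
    if failing:
        witnesses = tuple(
            _witness_for_suffix(taboo_set, suffix, max_n)
            for suffix, max_n in failing.items()
        )
        return ConnectivityVerdict(
            status=DISCONNECTED,
            rule="suffix_classification",
            left_proper=True,
            witnesses=witnesses,
            lsc=tuple(lsc),
            ssc=tuple(ssc),
            checked=tuple(checked),
            notes="; ".join(
                f"suffix {w.suffix!r} induces disconnected graphs for n >= {w.n}"
                for w in witnesses
            ),
        )
    return ConnectivityVerdict(
        status=ALL_CONNECTED,
        rule="suffix_classification",
        left_proper=True,
        lsc=tuple(lsc),
        ssc=tuple(ssc),
        checked=tuple(checked),
        notes="all classification checkpoint graphs are connected",
    )


def decide_connectivity(
    taboo_set: TabooSet, brute_bound: Optional[int] = None
) -> ConnectivityVerdict:
    """The full decision workflow.

    Applies, in order: taboo scarcity, psi pair synchronization, and -- for
    left proper taboo-sets -- the suffix classification characterization
    (which always decides).  A taboo-set that is not left proper falls back
    to a bounded brute-force search over the taboo suffixes: a disconnection
    found there is sound regardless of properness, while exhausting the
    bound returns ``undecided``.
    """
    verdict = check_taboo_scarcity(taboo_set)
    if verdict is not None:
        return verdict
    verdict = check_psi_pairs(taboo_set)
    if verdict is not None:
        return verdict
    if is_left_proper(taboo_set):
        return check_suffix_classification(taboo_set)

    M = taboo_set.M
    assert M is not None  # empty sets are settled by taboo scarcity
    bound = brute_bound if brute_bound is not None else M + 2
    suffixes = sorted(
        (s for s in taboo_set.suffix_set() if is_taboo_free(s, taboo_set)),
        key=lambda s: (len(s), taboo_set.alphabet.sort_key(s)),
    )
    for suffix in suffixes:
        max_n = len(suffix) + M + bound
        n = first_disconnected_n(taboo_set, suffix, max_n)
        if n is not None:
            comps = connected_components(build_suffix_graph(taboo_set, suffix, n))
            return ConnectivityVerdict(
                status=DISCONNECTED,
                rule="brute_force",
                left_proper=False,
                witnesses=(
                    Witness(suffix, n, comps[0][0], comps[1][0]),
                ),
                parameters={"brute_bound": bound},
                notes="disconnection found by bounded search (sound for any taboo-set)",
            )
    return ConnectivityVerdict(
        status=UNDECIDED,
        rule="brute_force",
        left_proper=False,
        parameters={"brute_bound": bound},
        notes=(
            "taboo-set is not left proper and the bounded search over taboo "
            "suffixes found no disconnection; the characterization does not apply"
        ),
    )


@dataclass(frozen=True)
class BruteForceReport:
    """Full connectivity table from the explicit BFS search."""

    table: dict  # (suffix, n) -> number of components
    first_disconnection: Optional[tuple[str, int]]

    @property
    def all_connected(self) -> bool:
        return self.first_disconnection is None


def brute_force_all_connected(
    taboo_set: TabooSet, max_suffix_len: int, max_n: int
) -> BruteForceReport:
    """Exhaustive explicit check: build every ``Gamma_n^s`` and run BFS.

    Scans lengths ``n`` in ascending order, suffix lengths ascending within
    each ``n``, suffixes in lexicographic order; the first disconnected graph
    encountered in that order is reported.  Empty graphs count as connected.
    """
    table: dict[tuple[str, int], int] = {}
    first: Optional[tuple[str, int]] = None
    suffixes_by_len = {
        j: enumerate_taboo_free(taboo_set, j) for j in range(max_suffix_len + 1)
    }
    for n in range(0, max_n + 1):
        for j in range(min(max_suffix_len, n) + 1):
            for suffix in suffixes_by_len[j]:
                graph = build_suffix_graph(taboo_set, suffix, n)
                ncomp = len(connected_components(graph))
                table[(suffix, n)] = ncomp
                if ncomp > 1 and first is None:
                    first = (suffix, n)
    return BruteForceReport(table=table, first_disconnection=first)


def exhaustive_scan(
    taboo_set: TabooSet,
    max_suffix_len: int,
    max_n: int,
    *,
    budget: int | None = 10_000_000,
) -> Optional[tuple[str, int]]:
    """First disconnected ``(suffix, n)`` by vectorized wildcard labeling.

    Independent of both the theorem-based engine (no quotient graphs, no
    classifications) and :func:`brute_force_all_connected` (no explicit
    edges): components are found by integer wildcard-key label propagation.
    Scan order matches the brute-force report, so the two agree exactly.
    """
    m = taboo_set.alphabet.m
    for n in range(0, max_n + 1):
        codes = taboo_free_codes(taboo_set, n, budget=budget)
        if codes.size == 0:
            continue
        for j in range(min(max_suffix_len, n) + 1):
            labels = suffix_component_labels(codes, n, m, j)
            bad = disconnected_suffix_codes(codes, labels, m, j)
            if bad.size:
                return decode(int(bad[0]), j, taboo_set.alphabet), n
    return None
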