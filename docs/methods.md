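# Methods

## Model

A taboo-set `T` over a finite ordered alphabet `Σ` (`|Σ| ≥ 2`) is a finite set
of forbidden substrings, each of length at least 2; `M` denotes the longest
taboo length. `V_n^s(T)` is the set of taboo-free strings of length `n` ending
in the (taboo-free) suffix `s`, and the suffix Hamming graph `Γ_n^s(T)` joins
two such strings when they differ at exactly one position. The package decides
whether every `Γ_n^s(T)` — over all taboo-free `s` and all `n` — is connected.

Biologically, taboos model type II restriction-enzyme recognition sites:
double-strandedness means a site forbids both itself and its reverse
complement, and sites that are inverted repeats (the typical case) contribute
a single taboo. The biological front-end is restricted to `{A, C, G, T}`;
the core engine accepts any alphabet of single-character symbols (e.g. a
fifth symbol for 5-methylcytosine), for which no reverse complement is
defined.

## Decision procedure

The engine applies three layers in fixed order (`decide_connectivity`):

1. `check_taboo_scarcity` — if the taboos' initial letters miss at least one
   symbol of `Σ`, any two taboo-free strings can be prefixed by a common safe
   symbol and connectivity of every suffix graph follows. `|T| < |Σ|` is a
   special case. The bound is tight: both `{10, 01}` over `{0,1}` and the
   three-symbol family `{a₃a₁, a₁a₂, a₂a₂}` have `|T| = |Σ|` and a
   disconnected (suffix) graph; both are regression-tested.
2. `check_psi_pairs` — the set `Ψ(T)` of taboos with their first symbol
   deleted is the exhaustive inventory of "one step from violating a taboo on
   the left" situations. If every taboo-free pair in `Ψ(T)` at truncated
   Hamming distance ≤ 1 (each member also paired with itself) is left
   1-synchronized, then every taboo-free string is 1-prefixable, distance-1
   pairs extend in lockstep, and all suffix graphs are connected by
   induction on length.
3. `check_suffix_classification` — for left proper `T`, the
   strip-suffix isomorphism `Γ_{n+|s|}^s ≅ Γ_{n+k_s}^{s[1,k_s]}` reduces all
   suffixes to the finite set `suf(V_M(T)) ∩ suf(T)`, split into the long
   classification `lsc` (canonical prefixes realized by some length-`M`
   string) and the short remainder `ssc`. Connectivity of all suffix graphs
   is equivalent to connectivity of the checkpoints indexed by these sets.
   The checkpoints are verified on **quotient graphs**: `Q[Γ^r_{M+|r|}]` over
   the 1-prefix partition for `r ∈ lsc` and `Q[Γ^p_{2M−1}]` over the
   `(M−|p|)`-prefix partition for `p ∈ ssc`, plus the explicit small graphs
   `Γ^p_n` for `|p|+2 ≤ n ≤ M−1` (an empty range when `M ≤ 3`). The quotient
   and full-graph forms of the characterization are equivalent; the quotient
   form is polynomially cheaper (its vertex count is at most `|Σ|^{M−1}` and
   each edge needs one set intersection of left extensions), which is what
   makes the randomized equivalence suite affordable. Witnesses are still
   extracted from explicit graphs.

A quotient-graph edge `{w₁, w₂}` exists iff `d(w₁, w₂) = 1` and `w₁s`, `w₂s`
share a left `(n−|s|−k)`-extension; blocks empty at length `n` are dropped so
the construction coincides with the graph-theoretic quotient of the explicit
suffix graph (empty blocks would otherwise appear as spuriously isolated
vertices).

**Witness policy.** All checkpoints are evaluated and each failing suffix `r`
yields one witness at the *smallest* length `n` with `Γ_n^r` disconnected
(found by explicit scan upward from `|r|`), reported as the lexicographically
smallest vertex of each of the first two components. This gives the
human-checkable "first break" rather than the checkpoint length itself, at
negligible cost since failures are verified on small graphs anyway.

**Non-left-proper sets.** The characterization is only proven under left
properness, and no general vertex-set-preserving rewriting into a left proper
set is available, so the engine does not attempt one. It falls back to a
bounded exhaustive search over the taboo suffixes up to length
`|r| + M + brute_bound` (default `brute_bound = M + 2`): a disconnection found
there is sound for any taboo-set; exhausting the bound returns `undecided`.
Soundness is preferred over completeness here.

## Independent oracles

Two exhaustive routes, sharing no code with the engine, validate it:

- `brute_force_all_connected` — builds every `Γ_n^s` explicitly (networkx)
  and counts components, returning a full table.
- `exhaustive_scan` — encodes vertices as base-`|Σ|` integers and labels
  components by wildcard-key min-label propagation: for each free position,
  all vertices agreeing everywhere else form a clique, so iterated
  group-minimum propagation (with pointer jumping) converges to component
  labels for *all* suffix graphs of one suffix length simultaneously, without
  materializing edges. This runs in roughly `O(n · N log N)` per sweep for
  `N` vertices and makes the 200-instance equivalence suite run in seconds.

A dedicated test pins the two oracles against each other on small instances;
the acceptance suite then pins `check_suffix_classification` against
`exhaustive_scan` over 200 seeded random left proper taboo-sets with
`|Σ| ∈ {2,3,4}`, taboo lengths ≤ 4 and at most 6 taboos, scanning all
suffixes `|s| ≤ M` and lengths `n ≤ 2M+1`. Both verdict classes
(connected/disconnected) must occur in the sample.

## Random fixtures

`generate_random_tabooset(alphabet_size, count, max_len, seed)` draws
`count` distinct taboos with lengths uniform in `[2, max_len]` by rejection
sampling from a `random.Random(seed)` stream; symbols are lowercase letters
to keep fixtures visually distinct from DNA. The equivalence suite draws
alphabet size, taboo count and maximal length from a separately seeded
stream and filters to left proper sets. These fixtures emulate the
*combinatorial* shape of recognition-site collections (few short forbidden
words over a small alphabet) but not their biological structure — no
reverse-complement closure, no inverted-repeat bias, no GC skew — so passing
the randomized suites demonstrates correctness of the decision machinery,
not coverage of any empirical distribution of real enzyme collections. The
named catalog sets cover the biologically structured cases.

## Tunable parameters

- `budget` (enumeration guard, default `10^7` candidate strings per
  extension step): refuses accidental exponential blow-ups; `budget=None`
  forces the computation. Purely protective — results never depend on it.
- `brute_bound` (fallback search depth, default `M + 2` extra lengths
  beyond `|r| + M`): how far past the guaranteed-persistence threshold the
  bounded search looks for non-left-proper sets. Larger values can only turn
  `undecided` into `disconnected`, never the reverse.
- `add_revcomp` (site expansion, default on): models double-strandedness;
  disable it to treat patterns as literal single-strand taboos.

## Numerical and determinism choices

- All sets are serialized in lexicographic order with respect to the
  alphabet's declared symbol order; components are sorted by smallest
  vertex. Verdicts are therefore bit-reproducible.
- Minimization processes candidate contraction roots in (length,
  lexicographic) order and restarts after each contraction; it is idempotent
  and preserves `V_n` for `n ≥ M` (property-tested). A contraction that
  would create a length-1 "taboo" is refused with a warning, since taboos
  are length ≥ 2 by definition.
- Synchronization queries with `k > M−1` over left proper sets are answered
  at `k = M−1` (provably equivalent for nonempty strings); other cases are
  enumerated directly.
- Degenerate inputs: the empty string is taboo-free; the empty taboo-set
  means "no constraints" and is trivially connected everywhere; empty graphs
  and single-vertex graphs count as connected; minimality and the suffix
  classification are undefined (raised) for the empty taboo-set;
  classification of a non-minimal set warns but proceeds.

## Known limitations

- The definitional scans (`is_minimal`, `compute_lsc`, left properness) are
  exponential in `M`; they are meant for recognition-site scale
  (`M ≤ ~8`, `|Σ| = 4`), where they take milliseconds, not for long taboos
  over large alphabets.
- For non-left-proper taboo-sets the engine is deliberately incomplete
  (`undecided` is a possible outcome); no rewriting into an equivalent left
  proper set is attempted.
- The problem sizes in the randomized suites (taboo length ≤ 4, ≤ 6 taboos,
  scan up to `n = 2M+1`) were chosen as the smallest regime in which every
  code path — including disconnections and nontrivial classifications — is
  exercised; the engine itself has no size-dependent logic.
- Enumeration is exact, not generating-function based; counting `|V_n|` for
  very large `n` is out of scope.
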