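# taboofree

Connectivity analysis of **taboo-free Hamming graphs**: sequence spaces that
avoid a set of forbidden substrings ("taboos").

## The problem

Bacterial restriction enzymes cut DNA at short recognition sites, so carrying
such a site can be lethal: each site is a *taboo* for the genome and for
infecting phage DNA. The space of viable sequences of length *n* is then the
set `V_n(T)` of strings over `Σ = {A, C, G, T}` containing no taboo of the set
`T`, and single point mutations trace walks on the **taboo-free Hamming graph**
`Γ_n(T)` — vertices `V_n(T)`, edges between strings at Hamming distance 1. If
some fragment is functionally conserved, evolution is confined to the suffix
subgraph `Γ_n^s(T)` of sequences ending in `s`.

Whether these graphs are *connected* decides whether point-mutation evolution
(or an MCMC sampler over viable sequences) can reach every viable sequence
from every other one. This package answers that question exactly.

## What it computes

Writing `M` for the longest taboo length, `L^k(s)` for the taboo-free left
*k*-extensions of `s`, and `suf(T)` for the proper suffixes of the taboos, the
decision procedure layers three criteria, cheapest first:

1. **Taboo scarcity.** If the taboos use fewer distinct initial letters than
   `|Σ|` (in particular if `|T| < |Σ|`), every `Γ_n^s(T)` is connected.
2. **Ψ pair synchronization.** Delete the first symbol of every taboo to form
   `Ψ(T)`. If every taboo-free pair `w₁, w₂ ∈ Ψ(T)` with
   `d(w₁[1,|w₂|], w₂) ≤ 1` shares a common one-symbol left extension, every
   `Γ_n^s(T)` is connected.
3. **Suffix classification.** For *left proper* `T` (every length-`M`
   taboo-free string extends one symbol to the left), each suffix `s` reduces
   to its canonical prefix `s[1, k_s] ∈ suf(T)`, with
   `Γ_{n+|s|}^s(T) ≅ Γ_{n+k_s}^{s[1,k_s]}(T)`. The canonical suffixes split
   into a long (`lsc`) and a short (`ssc`) classification, and *all* suffix
   graphs are connected **iff** finitely many checkpoint graphs are:
   `Γ^r_{M+|r|}` for `r ∈ lsc`, `Γ^p_{2M−1}` plus the small `Γ^p_n`
   (`|p|+2 ≤ n ≤ M−1`) for `p ∈ ssc`. A failed checkpoint yields a verified
   witness — two sequences that no viable mutation path connects.

Taboo-sets that are not left proper fall back to a bounded exhaustive search
(sound when it finds a disconnection, `undecided` otherwise).

The package also provides the supporting machinery as a library: taboo-set
minimization, vertex-set enumeration, `L^k`/`R^k` extensions,
synchronization tests, quotient graphs over *k*-prefix partitions, IUPAC
recognition-site expansion with reverse complements, and two independent
exhaustive oracles (explicit BFS, and a vectorized wildcard-key component
labeling) used to cross-validate the engine.

## Worked example

Two enzyme collections, audited from Python (`examples/restriction_site_audit.py`):

```text
two enzymes, GATC + GGWCC:
  taboos:  GATC, GGACC, GGTCC
  verdict: all_connected (rule: few_initial_letters)
four enzymes ending in CCC/GCC:
  taboos:  ACCC, CGCC, GGCC, GGCG, GGGA, GGGT, TCCC
  verdict: disconnected (rule: suffix_classification)
  witness: suffix 'CCC' at length 5: AGCCC and CCCCC lie in different components
```

The first collection (recognition sites `GATC` and degenerate `GGWCC`, plus
complementary strands) yields three taboos, all starting with `G`: criterion 1
applies and **every** suffix graph is connected. The second collection's seven
taboos disconnect the sequence space of strings ending in `CCC` from length 5
on: sequences ending `…GCCC` and `…CCCC` can never reach each other by viable
point mutations while the `CCC` suffix stays conserved — standard substitution
models of sequence evolution would silently assume an impossible path.

The same audit from the shell, with scriptable exit codes
(0 connected, 3 disconnected, 4 undecided, 2 input error):

```sh
taboofree check --sites sites.txt --revcomp --json verdict.json
```

Other example scripts: `examples/fibonacci_cubes.py` (enumeration sanity:
avoiding `11` over `{0,1}` gives Fibonacci-sized vertex sets),
`examples/suffix_classification.py` (the four checkpoint graphs of
`{AA, CCC}`), `examples/disconnection_witness.py` (the split suffix space
above, with both components listed).

## Layout

- `src/taboofree/core.py` — alphabets, taboo-sets, minimality, rewriting
- `src/taboofree/seqspace.py` — enumeration, `L^k`/`R^k`, `k_s`, properness,
  synchronization
- `src/taboofree/graphs.py` — suffix Hamming graphs, components, quotients
- `src/taboofree/classification.py` — canonical suffixes, `lsc`/`ssc`
- `src/taboofree/connectivity.py` — the decision procedure, witnesses, oracles
- `src/taboofree/biosites.py` — IUPAC sites, reverse complements, fixtures
- `src/taboofree/catalog.py` — the named example taboo-sets
- `src/taboofree/cli.py` — thin command-line wrapper
- `docs/methods.md` — model, assumptions, numerical choices, limitations
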