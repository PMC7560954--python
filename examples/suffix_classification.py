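"""Classify the suffix graphs of a small taboo-set up to isomorphism.

For {AA, CCC} the canonical suffixes are e, A, C and CC: every suffix graph
is isomorphic to one indexed by these, so checking four checkpoint graphs
settles the connectivity of infinitely many.
"""

from taboofree import TabooSet, check_suffix_classification, compute_ssc

taboo_set = TabooSet.from_strings({"AA", "CCC"})
result = compute_ssc(taboo_set)
print("long suffix classification: ", sorted(result.lsc, key=lambda s: (len(s), s)))
print("short suffix classification:", sorted(result.ssc, key=lambda s: (len(s), s)))

verdict = check_suffix_classification(taboo_set)
print(f"verdict: {verdict.status}")
print("checkpoint graphs examined (suffix, length):")
for suffix, n in verdict.checked:
    print(f"  ({suffix or 'e'}, {n})")
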