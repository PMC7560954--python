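"""Audit restriction-enzyme collections for sequence-space connectivity.

Builds the taboo-set each enzyme collection induces (IUPAC expansion plus
complementary-strand sequences) and runs the layered decision procedure.
"all_connected" means point mutations can reach every taboo-free sequence,
whatever suffix stays conserved; a witness pinpoints two sequences that can
never be connected by viable single substitutions.
"""

from taboofree import decide_connectivity, taboo_set_from_sites

collections = {
    "two enzymes, GATC + GGWCC": ["GATC", "GGWCC"],
    "four enzymes ending in CCC/GCC": ["ACCC", "TCCC", "CGCC", "GGCC"],
}

for name, sites in collections.items():
    taboo_set = taboo_set_from_sites(sites, add_revcomp=True)
    verdict = decide_connectivity(taboo_set)
    print(f"{name}:")
    print(f"  taboos:  {', '.join(taboo_set.sorted_taboos())}")
    print(f"  verdict: {verdict.status} (rule: {verdict.rule})")
    for w in verdict.witnesses:
        print(
            f"  witness: suffix {w.suffix!r} at length {w.n}: "
            f"{w.component_a_rep} and {w.component_b_rep} lie in different components"
        )
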