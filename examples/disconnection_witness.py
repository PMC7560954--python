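"""Find the exact point where a conserved suffix traps evolution.

The imaginary bacterium's seven taboos disconnect the sequence space of
strings ending in CCC: from length 5 on, GCCC-suffixed and CCCC-suffixed
sequences can no longer reach each other by viable point mutations.
"""

from taboofree import (
    build_suffix_graph,
    catalog,
    connected_components,
    first_disconnected_n,
)

taboo_set = catalog.bacterium_imaginara()
print("taboos:", ", ".join(taboo_set.sorted_taboos()))

n = first_disconnected_n(taboo_set, "CCC", max_n=10)
print(f"suffix graph of CCC first disconnects at length n = {n}")
for i, component in enumerate(connected_components(build_suffix_graph(taboo_set, "CCC", n)), 1):
    print(f"  component {i}: {', '.join(component)}")
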