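"""Count taboo-free binary strings avoiding 11: the Fibonacci cubes.

Forbidding the single taboo 11 over {0, 1} yields vertex sets whose sizes
are Fibonacci numbers -- the classic sanity check for the enumerator.
"""

from taboofree import Alphabet, TabooSet, enumerate_taboo_free

taboo_set = TabooSet(Alphabet.from_string("01"), frozenset({"11"}))
print("n  |V_n|  (Fibonacci numbers)")
for n in range(1, 13):
    print(f"{n:2d} {len(enumerate_taboo_free(taboo_set, n)):6d}")
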