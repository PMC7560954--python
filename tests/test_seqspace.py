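"""Sequence-space enumeration, prefixability, k_s and synchronization."""

import pytest

from taboofree import (
    Alphabet,
    TabooSet,
    are_left_k_synchronized,
    catalog,
    enumerate_taboo_free,
    is_left_proper,
    is_right_proper,
    is_suffix_viable,
    longest_taboo_suffix_prefix,
    prefix_extensions,
    suffix_extensions,
)
from taboofree.biosites import generate_random_tabooset
from taboofree.core import is_taboo_free
from taboofree.errors import EnumerationBudgetError, NotApplicableError


def brute_vertex_set(T, n, suffix=""):
    """Independent oracle: filter the full product space by substring scan."""
    import itertools

    out = []
    for tup in itertools.product(T.alphabet.symbols, repeat=n):
        s = "".join(tup)
        if s.endswith(suffix) and is_taboo_free(s, T):
            out.append(s)
    return out


class TestEnumeration:
    def test_antichain_leaves_only_constant_strings(self):
        T = catalog.antichain_example()
        assert enumerate_taboo_free(T, 4) == ["0000", "1111"]

    def test_length_equal_suffix_gives_single_vertex(self, aa_ccc):
        assert enumerate_taboo_free(aa_ccc, 2, "CC") == ["CC"]

    def test_matches_brute_force_filter(self):
        T = TabooSet.from_strings({"11", "000"}, "01")
        assert enumerate_taboo_free(T, 3) == ["001", "010", "100", "101"]
        for seed in range(8):
            R = generate_random_tabooset(2 + seed % 3, 1 + seed % 5, 3, seed)
            for n in range(0, 5):
                assert enumerate_taboo_free(R, n) == brute_vertex_set(R, n)

    def test_budget_guard_refuses_blowups(self):
        T = TabooSet.from_strings(set())
        with pytest.raises(EnumerationBudgetError):
            enumerate_taboo_free(T, 20, budget=1000)
        # and can be disabled explicitly on a tame instance
        assert len(enumerate_taboo_free(T, 5, budget=None)) == 4**5

    def test_fibonacci_vertex_counts(self, binary_fib):
        fib = [1, 1]
        while len(fib) < 20:
            fib.append(fib[-1] + fib[-2])
        for n in range(0, 16):
            assert len(enumerate_taboo_free(binary_fib, n)) == fib[n + 1]  # F_{n+2}

    def test_partition_by_k_prefixes(self):
        # |V_n^s| equals the sum of the block sizes over w in L^k(s)
        for seed in range(6):
            T = generate_random_tabooset(3, 3, 3, seed)
            for s in ["", "a"]:
                if not is_taboo_free(s, T):
                    continue
                for k in range(0, 3):
                    for n in range(len(s) + k, len(s) + k + 3):
                        total = len(enumerate_taboo_free(T, n, s))
                        blocks = sum(
                            len(enumerate_taboo_free(T, n, w + s))
                            for w in prefix_extensions(T, s, k)
                        )
                        assert total == blocks


class TestExtensions:
    def test_prefix_extension_examples(self):
        T = TabooSet.from_strings({"CAA", "GAA", "TAA"})
        assert prefix_extensions(T, "AA", 1) == {"A"}
        assert prefix_extensions(T, "AA", 2) == {"AA"}
        assert suffix_extensions(T, "AA", 1) == {"A", "C", "G", "T"}

    def test_three_letter_fan(self):
        T = TabooSet.from_strings({"ba", "aa", "ac", "cc"}, "abc")
        assert prefix_extensions(T, "b", 1) == {"a", "b", "c"}

    def test_zero_extension_is_empty_string(self, aa_ccc):
        assert prefix_extensions(aa_ccc, "CC", 0) == {""}
        assert suffix_extensions(aa_ccc, "CC", 0) == {""}

    def test_right_extensions_mirror_reversed_left_extensions(self):
        for seed in range(8):
            T = generate_random_tabooset(3, 3, 3, seed)
            rev = TabooSet(T.alphabet, frozenset(t[::-1] for t in T.taboos))
            for s in enumerate_taboo_free(T, 2):
                for k in range(0, 3):
                    mirrored = {
                        w[::-1] for w in prefix_extensions(rev, s[::-1], k)
                    }
                    assert suffix_extensions(T, s, k) == mirrored

    def test_splice_of_overlapping_taboo_free_strings(self):
        # if s1s2 and s2s3 are taboo-free and |s2| >= M-1, s1s2s3 is taboo-free
        import random

        for seed in range(10):
            T = generate_random_tabooset(3, 3, 3, seed)
            M = T.M
            rng = random.Random(seed)
            mids = enumerate_taboo_free(T, M - 1)
            if not mids:
                continue
            for _ in range(30):
                s2 = rng.choice(mids)
                lefts = enumerate_taboo_free(T, M + 1, s2)
                rights = suffix_extensions(T, s2, 2)
                if not lefts or not rights:
                    continue
                s1s2 = rng.choice(lefts)
                s3 = rng.choice(sorted(rights))
                assert is_taboo_free(s1s2 + s3, T)


class TestSuffixPrefixMatch:
    def test_longest_prefix_in_taboo_suffixes(self, aa_ccc):
        cls = longest_taboo_suffix_prefix(aa_ccc, "CCA")
        assert (cls.k, cls.canonical) == (2, "CC")

    def test_empty_string_matches_trivially(self, aa_ccc):
        assert longest_taboo_suffix_prefix(aa_ccc, "").k == 0

    def test_single_letter_match(self, dna_pairs):
        cls = longest_taboo_suffix_prefix(dna_pairs, "AC")
        assert (cls.k, cls.canonical) == (1, "A")

    def test_k_is_bounded_by_m_minus_one(self):
        for seed in range(8):
            T = generate_random_tabooset(3, 3, 3, seed)
            for s in enumerate_taboo_free(T, T.M):
                cls = longest_taboo_suffix_prefix(T, s)
                assert 0 <= cls.k <= min(T.M - 1, len(s))
                assert cls.canonical in T.suffix_set()

    def test_extensions_depend_only_on_the_canonical_prefix(self):
        # L^k(s) == L^k(s[1, k_s])
        for seed in range(8):
            T = generate_random_tabooset(3, 3, 3, seed)
            for s in enumerate_taboo_free(T, T.M + 1):
                cls = longest_taboo_suffix_prefix(T, s)
                for k in range(0, 5):
                    assert prefix_extensions(T, s, k) == prefix_extensions(
                        T, cls.canonical, k
                    )


class TestProperness:
    def test_all_first_letters_blocked_is_not_left_proper(self):
        T = TabooSet.from_strings({"AA", "CA", "GA", "TA"})
        assert not is_left_proper(T)
        assert is_right_proper(T)  # any string extends right by C

    def test_small_left_proper_set(self, aa_ccc):
        assert is_left_proper(aa_ccc)

    def test_cut_vertex_set_is_left_proper(self):
        # TTT is a taboo, hence not a vertex; everything else extends left
        assert is_left_proper(catalog.cut_vertex_example())

    def test_empty_taboo_set_is_trivially_proper(self):
        T = TabooSet.from_strings(set())
        assert is_left_proper(T) and is_right_proper(T)

    def test_properness_by_brute_force(self):
        for seed in range(12):
            T = generate_random_tabooset(2 + seed % 3, 1 + seed % 4, 3, seed)
            expected = all(
                prefix_extensions(T, s, 1) for s in enumerate_taboo_free(T, T.M)
            )
            assert is_left_proper(T) is expected

    def test_prefixability_extends_indefinitely_when_left_proper(self):
        # left proper + (|s| >= M or (M-|s|)-prefixable) => k-prefixable for all k
        for seed in range(10):
            T = generate_random_tabooset(3, 3, 3, seed)
            if not is_left_proper(T):
                continue
            M = T.M
            for s in enumerate_taboo_free(T, M) + enumerate_taboo_free(T, M - 1):
                if len(s) < M and not prefix_extensions(T, s, M - len(s)):
                    continue
                for k in range(1, M + 3):
                    assert prefix_extensions(T, s, k)


class TestViability:
    def test_long_suffixes_are_always_viable(self, aa_ccc):
        assert is_suffix_viable(aa_ccc, "CGC")

    def test_short_suffix_viability(self, aa_ccc):
        assert is_suffix_viable(aa_ccc, "CC")  # GCC realizes it in V_3

    def test_viability_predicts_nonempty_tail_spaces(self):
        for seed in range(10):
            T = generate_random_tabooset(2 + seed % 3, 1 + seed % 5, 3, seed)
            if not is_left_proper(T):
                continue
            M = T.M
            for j in range(0, M + 1):
                for s in enumerate_taboo_free(T, j):
                    nonempty = bool(enumerate_taboo_free(T, max(len(s), M) + 2, s))
                    assert is_suffix_viable(T, s) is nonempty

    def test_requires_left_proper(self):
        T = TabooSet.from_strings({"AA", "CA", "GA", "TA"})
        with pytest.raises(NotApplicableError):
            is_suffix_viable(T, "A")


class TestSynchronization:
    def test_imaginary_bacterium_blocking_pair(self, b_imaginara):
        assert not are_left_k_synchronized(b_imaginara, "CCC", "GCC", 1)

    def test_self_synchronization_is_prefixability(self, aa_ccc):
        for s in enumerate_taboo_free(aa_ccc, 3):
            assert are_left_k_synchronized(aa_ccc, s, s, 1) == bool(
                prefix_extensions(aa_ccc, s, 1)
            )

    def test_common_left_extension_example(self):
        T = TabooSet.from_strings({"AAA", "CCA", "GGA", "TTT"})
        assert are_left_k_synchronized(T, "AA", "CA", 1)  # T works for both

    def test_synchronization_at_m_minus_one_extends_beyond(self):
        # for left proper sets, (M-1)-synchronized pairs stay synchronized
        for seed in range(10):
            T = generate_random_tabooset(3, 3, 3, seed)
            if not is_left_proper(T):
                continue
            M = T.M
            strings = enumerate_taboo_free(T, M)
            for s1 in strings[:6]:
                for s2 in strings[:6]:
                    if are_left_k_synchronized(T, s1, s2, M - 1):
                        for k in range(M, M + 3):
                            direct = bool(
                                prefix_extensions(T, s1, k)
                                & prefix_extensions(T, s2, k)
                            )
                            assert direct
                            assert are_left_k_synchronized(T, s1, s2, k)
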