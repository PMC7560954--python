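"""Recognition-site handling: IUPAC expansion, reverse complements, fixtures.

Restriction enzymes recognize short double-stranded DNA motifs, often written
with IUPAC ambiguity codes (``GGWCC`` = ``GGACC`` or ``GGTCC``).  Because DNA
is double-stranded, a recognition site forbids both itself and its
complementary-strand sequence; a site equal to its own reverse complement
(an *inverted repeat*, the typical case for type II systems) induces a
single taboo.

All operations here are restricted to the ``{A, C, G, T}`` alphabet -- the
reverse complement is not defined for extended alphabets such as one with a
methylated cytosine -- while the core engine remains alphabet-generic.
"""

from __future__ import annotations

import itertools
import random
import string as _string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio.Data.IUPACData import ambiguous_dna_values

from .core import DNA, Alphabet, TabooSet
from .errors import InvalidSymbolError, InvalidTabooError

__all__ = [
    "RecognitionSite",
    "reverse_complement",
    "is_inverted_repeat",
    "expand_iupac",
    "taboo_set_from_sites",
    "read_sites_file",
    "generate_random_tabooset",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The four nucleotides plus the standard 11 ambiguity codes (no U, no X).
_IUPAC_CODES = {
    code: frozenset(ambiguous_dna_values[code])
    for code in "ACGTRYSWKMBDHVN"
}


def reverse_complement(s: str) -> str:
    """Complementary-strand sequence: reverse and substitute A<->T, C<->G.

    Ambiguity codes must be expanded first; only ``ACGT`` is accepted.
    """
    DNA.validate(s)
    return s.translate(_COMPLEMENT)[::-1]


def is_inverted_repeat(s: str) -> bool:
    """True iff the sequence equals its own reverse complement."""
    return s == reverse_complement(s)


def expand_iupac(pattern: str) -> set[str]:
    """All concrete ``ACGT`` sequences matching an IUPAC-degenerate pattern."""
    pattern = pattern.upper()
    choices = []
    for ch in pattern:
        if ch not in _IUPAC_CODES:
            raise InvalidSymbolError(
                f"unknown IUPAC nucleotide code {ch!r} in pattern {pattern!r}"
            )
        choices.append(sorted(_IUPAC_CODES[ch]))
    return {"".join(combo) for combo in itertools.product(*choices)}


@dataclass(frozen=True)
class RecognitionSite:
    """A (possibly degenerate) recognition site and its concrete expansion."""

    pattern: str

    @property
    def expansion(self) -> frozenset[str]:
        return frozenset(expand_iupac(self.pattern))

    @property
    def inverted_repeat(self) -> bool:
        """True iff the expansion is closed under reverse complement and each
        concrete sequence is its own reverse complement."""
        return all(is_inverted_repeat(s) for s in self.expansion)


def taboo_set_from_sites(
    sites: Sequence[str | RecognitionSite], add_revcomp: bool = True
) -> TabooSet:
    """Taboo-set induced by recognition sites over ``{A, C, G, T}``.

    Expands every IUPAC pattern and, when ``add_revcomp`` is set, adds the
    reverse complement of every concrete sequence; inverted repeats thus
    contribute a single taboo.
    """
    taboos: set[str] = set()
    for site in sites:
        pattern = site.pattern if isinstance(site, RecognitionSite) else site
        for seq in expand_iupac(pattern):
            if len(seq) < 2:
                raise InvalidTabooError(
                    f"site {pattern!r} expands to {seq!r}, shorter than a taboo"
                )
            taboos.add(seq)
            if add_revcomp:
                taboos.add(reverse_complement(seq))
    return TabooSet(DNA, frozenset(taboos))


def read_sites_file(path: str | Path) -> list[RecognitionSite]:
    """Read recognition sites: one IUPAC pattern per line, ``#`` comments."""
    sites = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            sites.append(RecognitionSite(line.upper()))
    return sites


def generate_random_tabooset(
    alphabet_size: int, count: int, max_len: int, seed: int
) -> TabooSet:
    """Deterministic random taboo-set for property tests and fixtures.

    Taboos are distinct, with lengths uniform in ``[2, max_len]``; symbols
    are lowercase letters so fixtures are visually distinct from DNA.
    """
    if alphabet_size < 2:
        raise ValueError("alphabet_size must be at least 2")
    if count < 1:
        raise ValueError("count must be at least 1")
    if max_len < 2:
        raise ValueError("max_len must be at least 2")
    if alphabet_size > 26:
        raise ValueError("at most 26 symbols are supported")
    symbols = _string.ascii_lowercase[:alphabet_size]
    available = sum(alphabet_size**l for l in range(2, max_len + 1))
    if count > available:
        raise ValueError(
            f"cannot draw {count} distinct taboos from {available} candidates"
        )
    rng = random.Random(seed)
    taboos: set[str] = set()
    while len(taboos) < count:
        length = rng.randint(2, max_len)
        taboos.add("".join(rng.choice(symbols) for _ in range(length)))
    return TabooSet(Alphabet.from_string(symbols), frozenset(taboos))
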