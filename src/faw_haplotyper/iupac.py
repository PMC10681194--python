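"""IUPAC nucleotide ambiguity-code algebra.

Directly sequenced PCR products from a diploid locus (here the two
Z-chromosomes of a male fall armyworm) superimpose the chromatogram traces
of both alleles; a heterozygous position appears as the IUPAC letter whose
state set is the union of the two allelic bases.  This module provides the
letter <-> state-set maps and the merge operation used both by the site
caller and the read simulator.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable

#: letter -> set of unambiguous bases it denotes
IUPAC_TO_STATES: dict[str, FrozenSet[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

STATES_TO_IUPAC: dict[FrozenSet[str], str] = {
    states: letter for letter, states in IUPAC_TO_STATES.items() if letter != "N"
}
STATES_TO_IUPAC[frozenset("ACGT")] = "N"

#: the full 15-letter alphabet accepted in read sequences
IUPAC_LETTERS = frozenset(IUPAC_TO_STATES)

UNAMBIGUOUS = frozenset("ACGT")


def decode(letter: str) -> FrozenSet[str]:
    """Return the set of bases encoded by a single IUPAC letter."""
    try:
        return IUPAC_TO_STATES[letter.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide letter: {letter!r}") from None


def encode(states: Iterable[str]) -> str:
    """Return the IUPAC letter for a non-empty set of bases."""
    key = frozenset(s.upper() for s in states)
    try:
        return STATES_TO_IUPAC[key]
    except KeyError:
        raise ValueError(f"no IUPAC letter for state set {sorted(key)}") from None


def merge_letters(a: str, b: str) -> str:
    """IUPAC letter representing the union of two letters' state sets.

    This models the superposition of two allelic traces at one position of a
    directly sequenced amplicon: C + T -> Y, A + A -> A, etc.
    """
    return encode(decode(a) | decode(b))


def is_valid_seq(seq: str) -> bool:
    return all(c in IUPAC_LETTERS for c in seq.upper())


def first_invalid_position(seq: str) -> int | None:
    """1-based position of the first non-IUPAC character, or None."""
    for i, c in enumerate(seq.upper(), start=1):
        if c not in IUPAC_LETTERS:
            return i
    return None
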