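"""IUPAC nucleotide-code arithmetic.

A degenerate oligonucleotide is synthesized as the equimolar mixture of all
plain-DNA sequences obtained by substituting each ambiguity code with one of
the bases it stands for.  Everything downstream (expansion counting, mismatch
profiling, effective-concentration penalties) reduces to set operations on the
per-position base sets defined here.
"""

from __future__ import annotations

import itertools

from Bio.Seq import reverse_complement as _bio_revcomp

#: base set encoded by each IUPAC nucleotide code
CODE_SETS: dict[str, frozenset[str]] = {
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

PLAIN_BASES = frozenset("ACGT")


def validate(sequence: str) -> None:
    """Raise ``ValueError`` naming the first position holding a non-IUPAC character."""
    for i, code in enumerate(sequence):
        if code not in CODE_SETS:
            raise ValueError(
                f"non-IUPAC character {code!r} at position {i} of {sequence!r}"
            )
    if len(sequence) < 1:
        raise ValueError("empty sequence")


def is_plain(sequence: str) -> bool:
    """True if the sequence contains only unambiguous bases A/C/G/T."""
    return all(b in PLAIN_BASES for b in sequence)


def degeneracy(sequence: str) -> int:
    """Number of plain sequences the degenerate sequence encodes.

    Product over positions of the cardinality of each code.
    """
    validate(sequence)
    n = 1
    for code in sequence:
        n *= len(CODE_SETS[code])
    return n


def expand(sequence: str) -> set[str]:
    """All distinct plain-DNA realizations of a degenerate sequence."""
    validate(sequence)
    return {
        "".join(bases)
        for bases in itertools.product(*(sorted(CODE_SETS[c]) for c in sequence))
    }


def matches(code: str, base: str) -> bool:
    """True if the plain template ``base`` lies within the primer ``code``'s base set."""
    return base in CODE_SETS[code]


def reverse_complement(sequence: str) -> str:
    """Reverse complement; ambiguity codes are complemented accordingly (R<->Y ...)."""
    return str(_bio_revcomp(sequence))
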