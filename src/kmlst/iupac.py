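"""IUPAC nucleotide ambiguity alphabet.

Diploid strains sequenced by Sanger chemistry show heterozygous positions as
two coincident peaks on both strands; such positions are recorded with the
one-letter IUPAC ambiguity codes (R = A/G, Y = C/T, ...). All sequence
comparison in this package treats an ambiguity code as the *set* of bases it
denotes, while genotype identity compares the literal characters.
"""

from __future__ import annotations

# code -> set of concrete bases (U is an alias for T, giving the 16-letter alphabet)
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
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

BASES_TO_CODE: dict[frozenset[str], str] = {
    v: k for k, v in CODE_TO_BASES.items() if k != "U"
}

IUPAC_ALPHABET: frozenset[str] = frozenset(CODE_TO_BASES)
CONCRETE_BASES: frozenset[str] = frozenset("ACGT")

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class AlphabetError(ValueError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


def validate_sequence(seq: str) -> str:
    """Uppercase *seq* and reject any non-IUPAC character."""
    seq = seq.upper()
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise AlphabetError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq


def bases(code: str) -> frozenset[str]:
    """The set of concrete bases an IUPAC code denotes."""
    try:
        return CODE_TO_BASES[code.upper()]
    except KeyError:
        raise AlphabetError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(base_set: frozenset[str] | set[str]) -> str:
    """The IUPAC code for a non-empty set of concrete bases."""
    try:
        return BASES_TO_CODE[frozenset(base_set)]
    except KeyError:
        raise AlphabetError(f"no IUPAC code for base set {sorted(base_set)}") from None


def complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[c] for c in seq.upper())
    except KeyError as exc:
        raise AlphabetError(f"non-IUPAC character: {exc.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement extended to the full ambiguity alphabet (involution)."""
    return complement(seq)[::-1]


def is_ambiguous(code: str) -> bool:
    return len(bases(code)) > 1


def expand(seq: str) -> list[str]:
    """All concrete A/C/G/T sequences compatible with an ambiguity-coded string."""
    out = [""]
    for c in seq:
        out = [p + b for p in out for b in sorted(bases(c))]
    return out
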