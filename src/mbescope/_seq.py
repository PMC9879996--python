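"""Low-level DNA alphabet helpers shared across the package.

Sequences handled here are plain uppercase strings over {A, C, G, T, N};
PAM patterns may use the full IUPAC nucleotide code. An ``N`` in a *sequence*
is treated as an unknown base and matches only an ``N`` in a *pattern* —
conservative behaviour for design use, where a placement should never rest
on an uncalled base.
"""

from __future__ import annotations

DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC = {
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


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, allow_n: bool = True, what: str = "sequence") -> str:
    """Uppercase *seq* and reject characters outside {A,C,G,T[,N]}."""
    seq = seq.upper()
    alphabet = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")
    return seq


def validate_iupac(pattern: str, what: str = "pattern") -> str:
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"{what} contains non-IUPAC letters: {sorted(bad)}")
    return pattern


def base_matches(seq_char: str, pat_char: str) -> bool:
    """Does one sequence base satisfy one IUPAC pattern letter?

    A sequence ``N`` matches only a pattern ``N``.
    """
    if seq_char == "N":
        return pat_char == "N"
    return seq_char in IUPAC[pat_char]


def pattern_matches_at(seq: str, start: int, pattern: str) -> bool:
    """Does *pattern* match *seq* starting at index *start* (no bounds slack)?"""
    if start < 0 or start + len(pattern) > len(seq):
        return False
    return all(
        base_matches(seq[start + i], pattern[i]) for i in range(len(pattern))
    )
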