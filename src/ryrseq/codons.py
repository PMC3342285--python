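"""Genetic-code and IUPAC nucleotide helpers shared across the package.

The standard (NCBI table 1) genetic code is taken from Biopython; this module
adds the small derived lookups the rest of the package needs: the 61 sense
codons in lexicographic order, a reverse (amino acid -> codons) table, the
minimal-degeneracy IUPAC back-translation of an amino acid, and bitmask
encodings of IUPAC codes used by the primer-matching routines.
"""

from __future__ import annotations

import math

from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, stops as '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.stop_codons))

#: the 61 sense codons, lexicographically sorted (A < C < G < T)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
)

#: amino acid -> lexicographically sorted tuple of its codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], tuple())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(AA_TO_CODONS))

#: IUPAC code -> set of concrete bases it covers
IUPAC_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in IUPACData.ambiguous_dna_values.items()
}
#: frozenset of bases -> the IUPAC code covering exactly that set
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}

#: IUPAC code -> 4-bit mask (A=1, C=2, G=4, T=8); used for vectorized matching
IUPAC_MASK: dict[str, int] = {
    code: sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in bases)
    for code, bases in IUPAC_BASES.items()
}


def smallest_codon(aa: str) -> str:
    """Lexicographically smallest codon encoding ``aa`` (deterministic plants)."""
    try:
        return AA_TO_CODONS[aa][0]
    except KeyError:
        raise ValueError(f"no codon encodes {aa!r}") from None


def degenerate_codon(aa: str) -> str:
    """Positionwise IUPAC codon covering every codon of ``aa``.

    E.g. L -> YTN (TTA/TTG/CTT/CTC/CTA/CTG), S -> WSN, W -> TGG.
    """
    codons = AA_TO_CODONS.get(aa)
    if not codons:
        raise ValueError(f"cannot back-translate {aa!r}: not a coding amino acid")
    return "".join(
        BASES_TO_IUPAC[frozenset(c[i] for c in codons)] for i in range(3)
    )


def translate_nt(seq: str) -> str:
    """Translate a stop-free coding sequence (length divisible by 3)."""
    if len(seq) % 3:
        raise ValueError("length not divisible by 3")
    return "".join(CODON_TO_AA[seq[i : i + 3]] for i in range(0, len(seq), 3))


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (N -> N, Y -> R, ...)."""
    return str(Seq(seq).reverse_complement())


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 rounding away from zero toward +inf."""
    return int(math.floor(x + 0.5))
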