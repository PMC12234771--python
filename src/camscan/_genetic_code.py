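"""Genetic-code constants for the bacterial/archaeal/plastid code (translation table 11).

All codon machinery in the package goes through this module so that the
synonymous-family structure (Leu/Ser/Arg six-fold, Ile three-fold, Met/Trp
singletons) is defined exactly once, derived from Biopython's codon tables.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: stop codons under table 11: TAA, TAG, TGA
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: codon -> one-letter amino acid, for the 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: the 61 sense codons, sorted
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> sorted tuple of synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in FAMILIES
}

#: degeneracy class (family size) per amino acid
FAMILY_SIZE: dict[str, int] = {aa: len(cods) for aa, cods in FAMILIES.items()}

#: single-codon families (Met ATG, Trp TGG) — excluded from RSCU preference,
#: SVC and CAM reporting because relative usage is uninformative there
SINGLETON_AAS: frozenset[str] = frozenset(
    aa for aa, k in FAMILY_SIZE.items() if k == 1
)
SINGLETON_CODONS: frozenset[str] = frozenset(
    c for c in SENSE_CODONS if CODON_TO_AA[c] in SINGLETON_AAS
)

#: sense codons that participate in RSCU/SVC/CAM reporting (59 of 61)
REPORTABLE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if c not in SINGLETON_CODONS
)

#: the five four-fold degenerate families used by the default PR2 accumulation
#: (Val, Pro, Thr, Ala, Gly)
FOURFOLD_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, k in FAMILY_SIZE.items() if k == 4)
)
FOURFOLD_CODONS: frozenset[str] = frozenset(
    c for aa in FOURFOLD_AAS for c in FAMILIES[aa]
)

#: amino acids by degeneracy class, for Wright's effective-number-of-codons sum
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {
    k: tuple(sorted(aa for aa, n in FAMILY_SIZE.items() if n == k))
    for k in (1, 2, 3, 4, 6)
}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def synonyms(codon: str) -> tuple[str, ...]:
    """All codons coding the same amino acid (including ``codon`` itself)."""
    return FAMILIES[CODON_TO_AA[codon]]
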