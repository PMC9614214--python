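"""Standard genetic code bookkeeping for synonymous-codon analyses.

Everything downstream works on the 59 "synonymous codons" (SCs): the 61
sense codons minus ATG (Met) and TGG (Trp), which have no synonyms. The
tables here are derived once from Biopython's standard codon table rather
than hard-coded.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: All 64 codons in a fixed canonical (alphabetical) order.
ALL_CODONS: tuple[str, ...] = tuple("".join(p) for p in product("ACGT", repeat=3))

#: The three stop codons.
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: codon -> one-letter amino acid, for the 61 sense codons.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: one-letter amino acid -> tuple of codons, alphabetical within family.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

#: The 18 amino acids encoded by >= 2 codons, alphabetical one-letter order.
SC_AMINO_ACIDS: tuple[str, ...] = tuple(
    aa for aa, codons in sorted(AA_TO_CODONS.items()) if len(codons) > 1
)

#: The 59 synonymous codons, canonical order.
SC_CODONS: tuple[str, ...] = tuple(
    c for c in ALL_CODONS if CODON_TO_AA.get(c) and len(AA_TO_CODONS[CODON_TO_AA[c]]) > 1
)

SC_SET: frozenset[str] = frozenset(SC_CODONS)

ONE_TO_THREE: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

assert len(SC_CODONS) == 59
assert len(SC_AMINO_ACIDS) == 18


def family(aa: str) -> tuple[str, ...]:
    """Codons of one amino-acid family (alphabetical)."""
    return AA_TO_CODONS[aa]


def ends_with(codon: str, bases: str) -> bool:
    return codon[2] in bases


def sc_ending_in(bases: str) -> tuple[str, ...]:
    """SCs whose third (wobble) base is one of ``bases``."""
    return tuple(c for c in SC_CODONS if c[2] in bases)


#: Degeneracy classes used by Wright's effective number of codons:
#: family size -> list of amino acids. Ile is the single 3-fold family.
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa in SC_AMINO_ACIDS:
    _k = len(AA_TO_CODONS[_aa])
    DEGENERACY_CLASSES.setdefault(_k, ())
    DEGENERACY_CLASSES[_k] += (_aa,)
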