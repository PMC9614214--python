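"""Sequence-context proxies for CpG-deamination-driven codon change.

Methylated cytosine deaminates to thymine. Inside a codon whose third base
pairs a CpG on the antisense strand (..NCG..), deamination converts NCG to
NCA; at a codon junction whose sense strand reads ..C|G.., it converts the
C-ending codon to its T-ending synonym (NC|G -> NT|G). Both events are
synonymous, so their footprints survive in codon usage:

* second-position table — counts of A-ending vs G-ending SCs keyed by
  their second base X (NXA, NXG); an inflated NCA/NCG ratio relative to
  NAA/NAG, NGA/NGG and NTA/NTG signals antisense-strand conversion;
* junction-triplet table — counts of NT|X vs NC|X over adjacent codon
  pairs; an inflated NT|G/NC|G ratio signals sense-strand conversion;
* per-amino-acid A/G-ending ratios for the codon pairs sharing their first
  two bases (Ala GCA/GCG, ..., Leu (TTA+CTA)/(TTG+CTG)), split into the
  NCA/NCG group (Ala, Pro, Ser, Thr) and the N(A/G/T)A/G group.

Junction pairs are eligible when the upstream codon is an SC ending T or C
and the downstream codon is not a stop; junctions are within-CDS (introns
are spliced out) and a junction is attributed to the exon of its upstream
codon when stratified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

from .codon_core import CodonCountTable
from .genetic_code import SC_SET, STOP_CODONS
from .genome_io import CdsRecord
from .strata import DEFAULT_MAX_EXONS

BASES = "ACGT"

#: amino acid -> (A-ending codons, G-ending codons) for the paired-ratio plot.
AA_PAIRS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "Ala": (("GCA",), ("GCG",)),
    "Pro": (("CCA",), ("CCG",)),
    "Ser": (("TCA",), ("TCG",)),
    "Thr": (("ACA",), ("ACG",)),
    "Lys": (("AAA",), ("AAG",)),
    "Glu": (("GAA",), ("GAG",)),
    "Gly": (("GGA",), ("GGG",)),
    "Arg": (("CGA", "AGA"), ("CGG", "AGG")),
    "Leu": (("TTA", "CTA"), ("TTG", "CTG")),
    "Val": (("GTA",), ("GTG",)),
}

#: amino acids whose pair has C at the second position (the CpG context).
NCA_NCG_GROUP = ("Ala", "Pro", "Ser", "Thr")


@dataclass
class SecondPositionTable:
    """Counts of A-/G-ending SCs by second base: nxa[X], nxg[X]."""

    nxa: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASES})
    nxg: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASES})

    def __add__(self, other: "SecondPositionTable") -> "SecondPositionTable":
        return SecondPositionTable(
            nxa={b: self.nxa[b] + other.nxa[b] for b in BASES},
            nxg={b: self.nxg[b] + other.nxg[b] for b in BASES},
        )


@dataclass
class JunctionTripletTable:
    """Counts of NT|X and NC|X junction pairs: ntx[X], ncx[X]."""

    ntx: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASES})
    ncx: dict[str, int] = field(default_factory=lambda: {b: 0 for b in BASES})

    def __add__(self, other: "JunctionTripletTable") -> "JunctionTripletTable":
        return JunctionTripletTable(
            ntx={b: self.ntx[b] + other.ntx[b] for b in BASES},
            ncx={b: self.ncx[b] + other.ncx[b] for b in BASES},
        )


def second_position_counts(table: CodonCountTable) -> SecondPositionTable:
    """NXA/NXG tallies over the A- and G-ending members of the 59 SCs."""
    out = SecondPositionTable()
    for codon in SC_SET:
        if codon[2] == "A":
            out.nxa[codon[1]] += table.counts[codon]
        elif codon[2] == "G":
            out.nxg[codon[1]] += table.counts[codon]
    return out


def nxa_nxg_ratios(s: SecondPositionTable) -> dict[str, float]:
    """ratio_X = NXA / NXG; NaN where NXG = 0."""
    return {
        b: (s.nxa[b] / s.nxg[b]) if s.nxg[b] > 0 else math.nan for b in BASES
    }


def _tally_junctions(
    codons: list[str],
    table: JunctionTripletTable,
    exon_index: list[int] | None = None,
    per_exon: dict[int, JunctionTripletTable] | None = None,
) -> None:
    for i in range(len(codons) - 1):
        prev_c, next_c = codons[i], codons[i + 1]
        if prev_c not in SC_SET or prev_c[2] not in "TC":
            continue
        if next_c in STOP_CODONS:
            continue
        x = next_c[0]
        target = table.ntx if prev_c[2] == "T" else table.ncx
        target[x] += 1
        if per_exon is not None and exon_index is not None:
            exon = exon_index[i]  # junction belongs to the upstream codon's exon
            cell = per_exon.setdefault(exon, JunctionTripletTable())
            tgt = cell.ntx if prev_c[2] == "T" else cell.ncx
            tgt[x] += 1


def junction_triplet_counts(records: Iterable[CdsRecord]) -> JunctionTripletTable:
    """NT|X / NC|X tallies over within-gene adjacent codon pairs."""
    table = JunctionTripletTable()
    for rec in records:
        if not rec.accepted:
            raise ValueError(f"record {rec.gene_id} is not accepted")
        _tally_junctions(rec.codons, table)
    return table


def ntx_ncx_ratios(j: JunctionTripletTable) -> dict[str, float]:
    """ratio_X = NT|X / NC|X; NaN where NC|X = 0."""
    return {
        b: (j.ntx[b] / j.ncx[b]) if j.ncx[b] > 0 else math.nan for b in BASES
    }


@dataclass
class AminoAcidPairRatio:
    amino_acid: str
    group: str  # "NCA/NCG" or "N(A/G/T)A/G"
    a_count: int
    g_count: int
    ratio: float


def per_aa_a_g_ratio(table: CodonCountTable) -> dict[str, AminoAcidPairRatio]:
    """A-ending over G-ending counts per paired amino acid (NaN if G = 0)."""
    out: dict[str, AminoAcidPairRatio] = {}
    for aa, (a_codons, g_codons) in AA_PAIRS.items():
        a = sum(table.counts[c] for c in a_codons)
        g = sum(table.counts[c] for c in g_codons)
        out[aa] = AminoAcidPairRatio(
            amino_acid=aa,
            group="NCA/NCG" if aa in NCA_NCG_GROUP else "N(A/G/T)A/G",
            a_count=a,
            g_count=g,
            ratio=a / g if g > 0 else math.nan,
        )
    return out


@dataclass
class StratifiedMethylation:
    """Methylation-context tables per exon-count stratum and per (e,p) cell."""

    second_by_stratum: dict[int, SecondPositionTable]
    junction_by_stratum: dict[int, JunctionTripletTable]
    second_by_cell: dict[tuple[int, int], SecondPositionTable]
    junction_by_cell: dict[tuple[int, int], JunctionTripletTable]


def methylation_by_strata(
    records: Iterable[CdsRecord], max_exons: int = DEFAULT_MAX_EXONS
) -> StratifiedMethylation:
    """Second-position and junction tables per stratum and per position cell.

    Genes with more than ``max_exons`` exons are excluded, mirroring the
    stratified counting. Junction pairs straddling an exon boundary count
    toward the upstream codon's exon.
    """
    from .codon_core import count_codons

    second_by_stratum: dict[int, SecondPositionTable] = {}
    junction_by_stratum: dict[int, JunctionTripletTable] = {}
    second_by_cell: dict[tuple[int, int], SecondPositionTable] = {}
    junction_by_cell: dict[tuple[int, int], JunctionTripletTable] = {}

    for rec in records:
        if not rec.accepted:
            raise ValueError(f"record {rec.gene_id} is not accepted")
        e = rec.n_exons
        if e > max_exons:
            continue
        codons = rec.codons
        gene_table = count_codons([rec])
        sp = second_position_counts(gene_table)
        second_by_stratum[e] = second_by_stratum.get(e, SecondPositionTable()) + sp

        per_exon_second: dict[int, SecondPositionTable] = {}
        for codon, p in zip(codons, rec.codon_exon_index):
            if codon in SC_SET and codon[2] in "AG":
                cell = per_exon_second.setdefault(p, SecondPositionTable())
                tgt = cell.nxa if codon[2] == "A" else cell.nxg
                tgt[codon[1]] += 1
        for p, sp_cell in per_exon_second.items():
            key = (e, p)
            second_by_cell[key] = second_by_cell.get(key, SecondPositionTable()) + sp_cell

        jt = JunctionTripletTable()
        per_exon_junction: dict[int, JunctionTripletTable] = {}
        _tally_junctions(codons, jt, rec.codon_exon_index, per_exon_junction)
        junction_by_stratum[e] = junction_by_stratum.get(e, JunctionTripletTable()) + jt
        for p, jt_cell in per_exon_junction.items():
            key = (e, p)
            junction_by_cell[key] = (
                junction_by_cell.get(key, JunctionTripletTable()) + jt_cell
            )

    return StratifiedMethylation(
        second_by_stratum=second_by_stratum,
        junction_by_stratum=junction_by_stratum,
        second_by_cell=second_by_cell,
        junction_by_cell=junction_by_cell,
    )
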