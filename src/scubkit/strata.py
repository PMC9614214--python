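"""Codon counts stratified by exon count and by exon position.

Genes are binned by the number of CDS-bearing exons of their selected
transcript (1..max_exons, default 10, larger genes in an overflow bucket).
Within a bin, codons can be further split by the exon each codon belongs to
under the split-codon rule, giving one count table per (exon_count,
position) cell. Both stratifications conserve counts exactly: cells sum
back to their stratum, strata plus overflow sum back to the genome table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .codon_core import CodonCountTable, ScubProfile, scub_profile
from .genetic_code import ALL_CODONS
from .genome_io import CdsRecord

DEFAULT_MAX_EXONS = 10


@dataclass
class ExonCountStrata:
    """exon_count -> CodonCountTable, plus an overflow bucket (> max)."""

    strata: dict[int, CodonCountTable]
    overflow: CodonCountTable
    max_exons: int = DEFAULT_MAX_EXONS

    def genome_table(self) -> CodonCountTable:
        total = CodonCountTable(scope="genome")
        for t in self.strata.values():
            total = total + t
        return total + self.overflow


@dataclass
class ExonPositionMatrix:
    """(exon_count e, position p in 1..e) -> CodonCountTable."""

    cells: dict[tuple[int, int], CodonCountTable]
    max_exons: int = DEFAULT_MAX_EXONS

    def stratum_table(self, e: int) -> CodonCountTable:
        total = CodonCountTable(scope=f"exons={e}")
        for (ee, _p), t in self.cells.items():
            if ee == e:
                total = total + t
        return total


def stratify_by_exon_count(
    records: Iterable[CdsRecord], max_exons: int = DEFAULT_MAX_EXONS
) -> ExonCountStrata:
    """Each gene contributes all its codons to the stratum of its exon count."""
    strata = {e: {c: 0 for c in ALL_CODONS} for e in range(1, max_exons + 1)}
    overflow = {c: 0 for c in ALL_CODONS}
    for rec in records:
        if not rec.accepted:
            raise ValueError(f"record {rec.gene_id} is not accepted")
        target = strata.get(rec.n_exons, overflow) if rec.n_exons <= max_exons else overflow
        for codon in rec.codons:
            target[codon] += 1
    return ExonCountStrata(
        strata={
            e: CodonCountTable(counts=c, scope=f"exons={e}")
            for e, c in strata.items()
        },
        overflow=CodonCountTable(counts=overflow, scope=f"exons>{max_exons}"),
        max_exons=max_exons,
    )


def stratify_by_exon_position(
    records: Iterable[CdsRecord], max_exons: int = DEFAULT_MAX_EXONS
) -> ExonPositionMatrix:
    """Codons binned by (gene's exon count, codon's exon index).

    Genes above ``max_exons`` are excluded (they only enter genome-wide
    statistics). Split codons were already resolved by
    :func:`scubkit.genome_io.assign_codons_to_exons`.
    """
    cells: dict[tuple[int, int], dict[str, int]] = {}
    for rec in records:
        if not rec.accepted:
            raise ValueError(f"record {rec.gene_id} is not accepted")
        e = rec.n_exons
        if e > max_exons:
            continue
        if not rec.codon_exon_index:
            raise ValueError(f"record {rec.gene_id} lacks codon_exon_index")
        for codon, p in zip(rec.codons, rec.codon_exon_index):
            key = (e, p)
            if key not in cells:
                cells[key] = {c: 0 for c in ALL_CODONS}
            cells[key][codon] += 1
    return ExonPositionMatrix(
        cells={
            k: CodonCountTable(counts=c, scope=f"exons={k[0]},pos={k[1]}")
            for k, c in cells.items()
        },
        max_exons=max_exons,
    )


def stratum_profiles(
    strata: ExonCountStrata | ExonPositionMatrix,
) -> dict[int, ScubProfile] | dict[tuple[int, int], ScubProfile]:
    """One ScubProfile per nonempty stratum or cell; empty cells are omitted."""
    if isinstance(strata, ExonCountStrata):
        return {
            e: scub_profile(t)
            for e, t in strata.strata.items()
            if t.sc_total > 0
        }
    return {
        key: scub_profile(t)
        for key, t in strata.cells.items()
        if t.sc_total > 0
    }


def middle_positions(e: int) -> tuple[int, ...]:
    """The central exon position(s) of an e-exon gene (both for even e)."""
    if e % 2 == 1:
        return ((e + 1) // 2,)
    return (e // 2, e // 2 + 1)


def interior_positions(e: int) -> tuple[int, ...]:
    """Internal exon positions 2..e-1 (empty for e < 3)."""
    return tuple(range(2, e))
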