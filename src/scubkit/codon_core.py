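"""Codon counting and synonymous codon usage statistics.

The central container is :class:`CodonCountTable`, integer counts over the
64 codons for any scope (genome, subgenome, stratum, single gene). Derived
statistics follow the usual SCUB definitions:

* per-amino-acid SCUB ratio — C/G-ending count over A/T-ending count within
  each of the 18 multi-codon families;
* third-base ending frequencies f(NNA)..f(NNG) over the 59 SCs, their
  pooled NNA/T and NNC/G forms, and the NNA/T : NNC/G ratio;
* RSCU — observed count over the within-family mean count;
* CAI — geometric mean of relative adaptiveness weights w (RSCU scaled by
  the family maximum on a reference table);
* ENC — Wright's effective number of codons (20 = one codon per family,
  61 = no bias), with the value capped at 61 as CodonW does.

Undefined quantities (zero denominators) are reported as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

from .genetic_code import (
    ALL_CODONS,
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    SC_AMINO_ACIDS,
    SC_CODONS,
    SC_SET,
    STOP_CODONS,
)
from .genome_io import CdsRecord


@dataclass
class CodonCountTable:
    """Integer counts over the 64 codons with a scope descriptor."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    scope: str = ""

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            if codon not in full:
                raise ValueError(f"unknown codon {codon!r}")
            if n < 0:
                raise ValueError(f"negative count for {codon}")
            full[codon] = int(n)
        self.counts = full

    def __getitem__(self, codon: str) -> int:
        return self.counts[codon]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def sc_total(self) -> int:
        return sum(self.counts[c] for c in SC_CODONS)

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(
            counts={c: self.counts[c] + other.counts[c] for c in ALL_CODONS},
            scope=self.scope,
        )

    def ending_count(self, bases: str) -> int:
        """Count of SCs whose third base is in ``bases``."""
        return sum(self.counts[c] for c in SC_CODONS if c[2] in bases)

    def to_series(self):
        import pandas as pd

        return pd.Series(self.counts, name=self.scope or "count")


@dataclass
class ScubProfile:
    """Derived SCUB statistics of one count table (one scope)."""

    per_aa_ratio: dict[str, float]  # aa -> C/G-ending : A/T-ending counts
    ending_freq: dict[str, float]  # base -> f(NN<base>) over the 59 SCs
    combined: dict[str, float]  # {"AT": f(NNA/T), "CG": f(NNC/G)}
    at_cg_ratio: float  # (fNNA + fNNT) / (fNNC + fNNG)

    @property
    def cg_at_ratio(self) -> float:
        return 1.0 / self.at_cg_ratio if self.at_cg_ratio > 0 else math.nan


def count_codons(records: Iterable[CdsRecord], scope: str = "") -> CodonCountTable:
    """Tally every in-frame codon of every accepted record."""
    counts = {c: 0 for c in ALL_CODONS}
    for rec in records:
        if not rec.accepted:
            raise ValueError(f"record {rec.gene_id} is not accepted")
        for codon in rec.codons:
            counts[codon] += 1
    return CodonCountTable(counts=counts, scope=scope)


def codon_frequencies(
    table: CodonCountTable,
    scope_mode: Literal["all64", "nonstop61", "sc59"] = "sc59",
) -> dict[str, float]:
    """Codon frequencies under one of three denominators.

    ``all64``/``nonstop61``: each (non-stop) codon over the total number of
    codons. ``sc59``: each SC over the number of SCs. All-zero denominators
    yield NaN for every reported codon.
    """
    if scope_mode in ("all64", "nonstop61"):
        denom = table.total
        codons = ALL_CODONS if scope_mode == "all64" else tuple(
            c for c in ALL_CODONS if c not in STOP_CODONS
        )
    elif scope_mode == "sc59":
        denom = table.sc_total
        codons = SC_CODONS
    else:
        raise ValueError(f"unknown scope_mode {scope_mode!r}")
    if denom == 0:
        return {c: math.nan for c in codons}
    return {c: table.counts[c] / denom for c in codons}


def per_aa_scub_ratio(table: CodonCountTable) -> dict[str, float]:
    """C/G-ending over A/T-ending SC count per amino acid (NaN if A/T = 0)."""
    ratios: dict[str, float] = {}
    for aa in SC_AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        cg = sum(table.counts[c] for c in codons if c[2] in "CG")
        at = sum(table.counts[c] for c in codons if c[2] in "AT")
        ratios[aa] = cg / at if at > 0 else math.nan
    return ratios


def scub_profile(table: CodonCountTable) -> ScubProfile:
    """Ending frequencies and ratios over the 59-SC universe."""
    sc_total = table.sc_total
    if sc_total == 0:
        raise ValueError(f"no synonymous codons in scope {table.scope!r}")
    ending = {b: table.ending_count(b) / sc_total for b in "ATCG"}
    combined = {"AT": ending["A"] + ending["T"], "CG": ending["C"] + ending["G"]}
    at_cg = combined["AT"] / combined["CG"] if combined["CG"] > 0 else math.nan
    return ScubProfile(
        per_aa_ratio=per_aa_scub_ratio(table),
        ending_freq=ending,
        combined=combined,
        at_cg_ratio=at_cg,
    )


def rscu(table: CodonCountTable) -> dict[str, float]:
    """Relative synonymous codon usage for the 59 SCs.

    RSCU_c = count_c / (family_total / family_size); a family with zero
    total gets NaN for all its codons.
    """
    values: dict[str, float] = {}
    for aa in SC_AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        family_total = sum(table.counts[c] for c in codons)
        for c in codons:
            if family_total == 0:
                values[c] = math.nan
            else:
                values[c] = table.counts[c] / (family_total / len(codons))
    return values


def reference_weights(
    table: CodonCountTable, zero_count_floor: float = 0.01
) -> dict[str, float]:
    """Relative adaptiveness w per SC: RSCU scaled by the family maximum.

    A codon unobserved in an otherwise observed family gets the small floor
    weight (default 0.01) so CAI's log never diverges; families entirely
    absent from the reference get NaN (such codons are skipped by CAI).
    """
    r = rscu(table)
    weights: dict[str, float] = {}
    for aa in SC_AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        family_max = max(
            (r[c] for c in codons if not math.isnan(r[c])), default=math.nan
        )
        for c in codons:
            if math.isnan(r[c]) or family_max == 0 or math.isnan(family_max):
                weights[c] = math.nan
            elif r[c] == 0:
                weights[c] = zero_count_floor
            else:
                weights[c] = r[c] / family_max
    return weights


@dataclass
class CaiResult:
    value: float
    codons_used: int


def cai(gene: CodonCountTable, weights: Mapping[str, float]) -> CaiResult:
    """Codon adaptation index: geometric mean of w over the gene's SCs.

    ATG, TGG and stops never contribute; codons with undefined (NaN)
    weight are skipped and reflected in ``codons_used``.
    """
    log_sum = 0.0
    n = 0
    for c in SC_CODONS:
        k = gene.counts[c]
        if k == 0:
            continue
        w = weights.get(c, math.nan)
        if w is None or math.isnan(w):
            continue
        log_sum += k * math.log(w)
        n += k
    if n == 0:
        raise ValueError("gene has no synonymous codons with defined weights")
    return CaiResult(value=math.exp(log_sum / n), codons_used=n)


def enc(table: CodonCountTable) -> float:
    """Wright's effective number of codons, capped to [20, 61].

    Per family: F = (n * sum(p_i^2) - 1) / (n - 1) with n the family total
    and p_i the within-family codon proportions. Class means of F over
    2-, 3-, 4- and 6-fold degenerate families enter
    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6. Families with n < 2 or F <= 0 are
    left out of their class mean; a class with no defined family borrows
    the mean F of all defined families (documented fallback).
    """
    class_f: dict[int, list[float]] = {k: [] for k in DEGENERACY_CLASSES}
    all_f: list[float] = []
    for k, aas in DEGENERACY_CLASSES.items():
        for aa in aas:
            counts = np.array([table.counts[c] for c in AA_TO_CODONS[aa]], dtype=float)
            n = counts.sum()
            if n < 2:
                continue
            p = counts / n
            f = (n * float(np.sum(p * p)) - 1.0) / (n - 1.0)
            if f <= 0:
                continue
            class_f[k].append(f)
            all_f.append(f)
    if not all_f:
        return math.nan
    fallback = float(np.mean(all_f))
    value = 2.0
    n_families = {2: 9, 3: 1, 4: 5, 6: 3}
    for k, n_fam in n_families.items():
        fs = class_f.get(k, [])
        f_bar = float(np.mean(fs)) if fs else fallback
        value += n_fam / f_bar
    return min(max(value, 20.0), 61.0)


def gc3s(table: CodonCountTable) -> float:
    """G+C fraction at third positions of the 59 SCs (NaN if none)."""
    sc_total = table.sc_total
    if sc_total == 0:
        return math.nan
    return table.ending_count("GC") / sc_total
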