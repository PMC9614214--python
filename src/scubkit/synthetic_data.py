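"""Synthetic genomes with known codon-usage structure.

The generator emulates exactly the statistical features the analysis
measures, so every pipeline stage has a closed-form or recorded oracle:

* multi-exon gene models (ATG + drawn codons + stop, introns inserted at
  uniform inter-nucleotide positions so both 1|2 and 2|3 codon splits
  arise naturally);
* per-amino-acid codon usage with a controllable third-base C/G odds
  multiplier (``cg_odds``), optionally overridden by explicit family
  distributions;
* an interior-exon A/T tilt ``interior_tilt`` multiplying A/T-ending odds
  for codons whose exon is neither first nor last;
* a CpG-deamination process converting NCG -> NCA with probability
  ``m_anti`` (antisense-strand methylation) and C-ending codons followed
  by a G-starting codon to their T-ending synonym with probability
  ``m_sense`` (sense-strand methylation). Both conversions are synonymous
  by the structure of the standard code, asserted at run time.

Genes use per-gene random substreams keyed by (seed, gene index), so
changing ``n_genes`` never reshuffles earlier genes, and output is
byte-identical for a fixed config.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .genetic_code import ALL_CODONS, AA_TO_CODONS, CODON_TO_AA, SC_SET, STOP_CODONS
from .methylation import SecondPositionTable

_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}
_STOPS = ("TAA", "TAG", "TGA")

# Conversion lookup tables over codon indices.
_IS_NCG = np.array([c[1] == "C" and c[2] == "G" for c in ALL_CODONS])
_NCG_TO_NCA = np.array(
    [_CODON_INDEX[c[:2] + "A"] if _IS_NCG[i] else i for i, c in enumerate(ALL_CODONS)]
)
_ENDS_C = np.array([c[2] == "C" for c in ALL_CODONS])
_STARTS_G = np.array([c[0] == "G" for c in ALL_CODONS])
_C_TO_T = np.array(
    [_CODON_INDEX[c[:2] + "T"] if _ENDS_C[i] else i for i, c in enumerate(ALL_CODONS)]
)

_AA20 = tuple(sorted(AA_TO_CODONS))  # 20 one-letter amino acids


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic species.

    Defaults describe the study conditions used throughout the tests: 200
    genes of 100-300 internal codons, exon counts uniform on 1..10, a
    1.5-fold odds preference for C/G-ending codons (the NNC/G bias typical
    of a wheat-like genome), no positional tilt and no deamination.
    """

    seed: int
    n_genes: int = 200
    exon_count_probs: dict[int, float] = field(
        default_factory=lambda: {e: 0.1 for e in range(1, 11)}
    )
    codons_min: int = 100
    codons_max: int = 300
    aa_weights: dict[str, float] | None = None  # default: uniform over 20 aa
    cg_odds: float = 1.5
    family_probs: dict[str, dict[str, float]] | None = None
    interior_tilt: float = 1.0
    m_anti: float = 0.0
    m_sense: float = 0.0
    intron_min: int = 60
    intron_max: int = 200
    spacer: int = 100
    chromosomes: tuple[str, ...] = ("chr1A",)
    minus_strand_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("m_anti", "m_sense", "minus_strand_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.interior_tilt < 0:
            raise ValueError("interior_tilt must be non-negative")
        total = sum(self.exon_count_probs.values())
        if total <= 0:
            raise ValueError("exon_count_probs must have positive mass")
        self.exon_count_probs = {
            e: p / total for e, p in sorted(self.exon_count_probs.items()) if p > 0
        }


def codon_probabilities(config: SimulationConfig, interior: bool = False) -> np.ndarray:
    """Per-draw probability over the 64 codons for one positional context.

    Stops get zero mass (drawn separately); within each family A/T-ending
    codons carry weight 1 and C/G-ending codons ``cg_odds`` unless explicit
    ``family_probs`` are given; interior context multiplies A/T-ending
    weights by ``interior_tilt`` and renormalizes within the family.
    """
    aa_w = config.aa_weights or {aa: 1.0 for aa in _AA20}
    total_aa = sum(aa_w.values())
    p = np.zeros(64)
    for aa, codons in AA_TO_CODONS.items():
        w_aa = aa_w.get(aa, 0.0) / total_aa
        if w_aa == 0:
            continue
        if config.family_probs and aa in config.family_probs:
            fam = dict(config.family_probs[aa])
            missing = set(codons) - set(fam)
            if missing:
                fam.update({c: 0.0 for c in missing})
        else:
            fam = {c: (config.cg_odds if c[2] in "CG" else 1.0) for c in codons}
        if interior and config.interior_tilt != 1.0:
            fam = {
                c: (w * config.interior_tilt if c[2] in "AT" else w)
                for c, w in fam.items()
            }
        z = sum(fam.values())
        if z <= 0:
            raise ValueError(f"family distribution for {aa} has no mass")
        for c in codons:
            p[_CODON_INDEX[c]] = w_aa * fam[c] / z
    return p / p.sum()


def apply_conversions(
    codon_idx: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, int, int]:
    """CpG-deamination conversions on one CDS body (array of codon indices).

    NCG -> NCA with probability ``m_anti`` per eligible codon, then
    C-ending codons whose successor starts with G flip to the T-ending
    synonym with probability ``m_sense``. Returns (converted array,
    n_anti_events, n_sense_events).
    """
    out = codon_idx.copy()
    n_anti = n_sense = 0
    if config.m_anti > 0:
        mask = _IS_NCG[out]
        flips = mask & (rng.random(out.size) < config.m_anti)
        n_anti = int(flips.sum())
        out[flips] = _NCG_TO_NCA[out[flips]]
    if config.m_sense > 0 and out.size > 1:
        mask = _ENDS_C[out[:-1]] & _STARTS_G[out[1:]]
        flips = mask & (rng.random(out.size - 1) < config.m_sense)
        n_sense = int(flips.sum())
        prev = out[:-1]
        prev[flips] = _C_TO_T[prev[flips]]
        out[:-1] = prev
    return out, n_anti, n_sense


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    chromosome: str
    strand: str
    exon_count: int
    segment_lengths: list[int]
    pre_codons: list[str]
    post_codons: list[str]
    codon_exon_index: list[int]
    n_anti_events: int
    n_sense_events: int

    @property
    def cds_sequence(self) -> str:
        return "".join(self.post_codons)


@dataclass
class SimulatedGenome:
    """A synthetic species: FASTA sequences, GFF3 text and per-gene truth."""

    config: SimulationConfig
    sequences: dict[str, str]
    gff3_text: str
    genes: list[GeneTruth]

    @property
    def fasta_text(self) -> str:
        lines: list[str] = []
        for name, seq in self.sequences.items():
            lines.append(f">{name}")
            lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
        return "\n".join(lines) + "\n"

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        fasta_path = directory / "genome.fasta"
        gff3_path = directory / "annotation.gff3"
        fasta_path.write_text(self.fasta_text)
        gff3_path.write_text(self.gff3_text)
        return fasta_path, gff3_path


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _translate(codons: list[str]) -> str:
    return "".join(
        "*" if c in STOP_CODONS else CODON_TO_AA[c] for c in codons
    )


def simulate_gene(
    config: SimulationConfig,
    gene_index: int,
    p_base: np.ndarray,
    p_interior: np.ndarray,
) -> tuple[GeneTruth, str, list[tuple[int, int]], str, str]:
    """One gene: truth plus its genomic fragment and segment offsets.

    Returns (truth, fragment sequence in sense orientation, 1-based
    sense-coordinate CDS segments within the fragment, strand, spacer).
    """
    rng = np.random.default_rng([config.seed, gene_index])
    exon_counts = np.array(list(config.exon_count_probs))
    exon_probs = np.array(list(config.exon_count_probs.values()))
    e = int(rng.choice(exon_counts, p=exon_probs))
    n_body = int(rng.integers(config.codons_min, config.codons_max + 1))
    n_codons = n_body + 2
    cds_len = 3 * n_codons

    if e > 1:
        cuts = np.sort(rng.choice(cds_len - 1, size=e - 1, replace=False) + 1)
    else:
        cuts = np.array([], dtype=int)
    bounds = np.concatenate([cuts, [cds_len]])  # cumulative exon ends
    segment_lengths = np.diff(np.concatenate([[0], bounds])).tolist()

    # Codon -> exon: the exon containing the codon's second nucleotide.
    mids = 3 * np.arange(n_codons) + 2
    exon_index = np.searchsorted(bounds, mids, side="left") + 1
    interior = (exon_index > 1) & (exon_index < e)

    body_base = rng.choice(64, size=n_body, p=p_base)
    body_int = rng.choice(64, size=n_body, p=p_interior)
    body = np.where(interior[1:-1], body_int, body_base)
    stop = _STOPS[int(rng.integers(0, 3))]
    pre_idx = np.concatenate(
        [[_CODON_INDEX["ATG"]], body, [_CODON_INDEX[stop]]]
    )
    post_idx, n_anti, n_sense = apply_conversions(pre_idx, config, rng)

    pre_codons = [ALL_CODONS[i] for i in pre_idx]
    post_codons = [ALL_CODONS[i] for i in post_idx]
    if _translate(pre_codons) != _translate(post_codons):
        raise AssertionError("conversion changed the protein sequence")

    cds = "".join(post_codons)
    segments: list[tuple[int, int]] = []
    fragment_parts: list[str] = []
    offset = 0  # current fragment length
    start = 1
    for length in segment_lengths:
        fragment_parts.append(cds[start - 1 : start - 1 + length])
        segments.append((offset + 1, offset + length))
        offset += length
        start += length
        if start <= cds_len:  # intron after every non-terminal exon
            ilen = int(rng.integers(config.intron_min, config.intron_max + 1))
            fragment_parts.append(_random_bases(rng, ilen))
            offset += ilen
    fragment = "".join(fragment_parts)
    strand = "-" if rng.random() < config.minus_strand_prob else "+"
    spacer = _random_bases(rng, config.spacer)
    chromosome = config.chromosomes[gene_index % len(config.chromosomes)]
    truth = GeneTruth(
        gene_id=f"g{gene_index:05d}",
        chromosome=chromosome,
        strand=strand,
        exon_count=e,
        segment_lengths=segment_lengths,
        pre_codons=pre_codons,
        post_codons=post_codons,
        codon_exon_index=exon_index.tolist(),
        n_anti_events=n_anti,
        n_sense_events=n_sense,
    )
    return truth, fragment, segments, strand, spacer


_REVCOMP = str.maketrans("ACGT", "TGCA")


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate FASTA + GFF3 + truth for one synthetic species."""
    p_base = codon_probabilities(config, interior=False)
    p_interior = codon_probabilities(config, interior=True)
    chrom_seqs: dict[str, list[str]] = {c: [] for c in config.chromosomes}
    chrom_len: dict[str, int] = {c: 0 for c in config.chromosomes}
    gff_lines: dict[str, list[str]] = {c: [] for c in config.chromosomes}
    genes: list[GeneTruth] = []

    for i in range(config.n_genes):
        truth, fragment, segments, strand, spacer = simulate_gene(
            config, i, p_base, p_interior
        )
        chrom = truth.chromosome
        chrom_seqs[chrom].append(spacer)
        chrom_len[chrom] += len(spacer)
        offset = chrom_len[chrom]
        m = len(fragment)
        placed = fragment if strand == "+" else fragment.translate(_REVCOMP)[::-1]
        chrom_seqs[chrom].append(placed)
        chrom_len[chrom] += m

        genomic_segments: list[tuple[int, int]] = []
        for s, t in segments:
            if strand == "+":
                genomic_segments.append((offset + s, offset + t))
            else:
                genomic_segments.append((offset + m - t + 1, offset + m - s + 1))
        genomic_segments.sort()
        g_start, g_end = offset + 1, offset + m
        gid, tid = truth.gene_id, f"t{i:05d}"
        gff_lines[chrom].append(
            f"{chrom}\tscubkit\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gid}"
        )
        gff_lines[chrom].append(
            f"{chrom}\tscubkit\tmRNA\t{g_start}\t{g_end}\t.\t{strand}\t.\t"
            f"ID={tid};Parent={gid}"
        )
        for s, t in genomic_segments:
            gff_lines[chrom].append(
                f"{chrom}\tscubkit\tCDS\t{s}\t{t}\t.\t{strand}\t0\tParent={tid}"
            )
        genes.append(truth)

    sequences = {c: "".join(parts) for c, parts in chrom_seqs.items()}
    lines = ["##gff-version 3"]
    for c in config.chromosomes:
        lines.extend(gff_lines[c])
    return SimulatedGenome(
        config=config,
        sequences=sequences,
        gff3_text="\n".join(lines) + "\n",
        genes=genes,
    )


def simulate_sc_draws(
    config: SimulationConfig, n_codons: int, seed: int | None = None
) -> np.ndarray:
    """Fast path: one long converted CDS body as an array of codon indices.

    Draws ``n_codons`` codons from the baseline (terminal-exon)
    distribution and applies both conversion processes, treating the array
    as a single uninterrupted coding frame. Used for large-sample rate
    recovery where full gene models are unnecessary.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p_base = codon_probabilities(config, interior=False)
    idx = rng.choice(64, size=n_codons, p=p_base)
    out, _, _ = apply_conversions(idx, config, rng)
    return out


def second_position_table_from_indices(codon_idx: np.ndarray) -> SecondPositionTable:
    """SecondPositionTable from an array of codon indices."""
    table = SecondPositionTable()
    counts = np.bincount(codon_idx, minlength=64)
    for i, c in enumerate(ALL_CODONS):
        if c not in SC_SET:
            continue
        if c[2] == "A":
            table.nxa[c[1]] += int(counts[i])
        elif c[2] == "G":
            table.nxg[c[1]] += int(counts[i])
    return table


def truth_records(genome: SimulatedGenome) -> list:
    """Accepted CdsRecords built directly from a genome's truth tables.

    Bypasses FASTA/GFF3 round-tripping for experiments that only need the
    downstream statistics (the file round trip is exercised separately).
    """
    from .genome_io import CdsRecord

    records = []
    for gene in genome.genes:
        rec = CdsRecord(
            gene_id=gene.gene_id,
            transcript_id=gene.gene_id,
            chromosome=gene.chromosome,
            cds_sequence=gene.cds_sequence,
            segment_lengths=list(gene.segment_lengths),
            species_label="synthetic",
            status="accepted",
            codon_exon_index=list(gene.codon_exon_index),
        )
        records.append(rec)
    return records


@dataclass
class ExpectedRatios:
    """Closed-form post-conversion expectations under a config."""

    nxa_nxg: dict[str, float]
    ntx_ncx: dict[str, float]
    ending_freq: dict[str, float]
    at_cg_ratio: float


def expected_ratios(config: SimulationConfig) -> ExpectedRatios:
    """Expected NXA/NXG, NT|X/NC|X and ending frequencies per body draw.

    Uses the baseline (non-interior) codon distribution. Per draw,
    E[NCA] = p_NCA + m_anti * p_NCG and E[NCG] = (1 - m_anti) * p_NCG; the
    junction NT|G/NC|G ratio is (p_T + m_sense * p_C) / ((1 - m_sense) *
    p_C) because the next-codon start factor cancels, while the other
    junction ratios stay at p_T / p_C. Ending frequencies fold in the
    sense-strand flux p_C * m_sense * p(start G).
    """
    p = codon_probabilities(config, interior=False)
    post = p.copy()
    moved = config.m_anti * post[_IS_NCG]
    post[_IS_NCG] -= moved
    nca_targets = _NCG_TO_NCA[_IS_NCG]
    np.add.at(post, nca_targets, moved)

    nxa = {b: 0.0 for b in "ACGT"}
    nxg = {b: 0.0 for b in "ACGT"}
    for i, c in enumerate(ALL_CODONS):
        if c not in SC_SET:
            continue
        if c[2] == "A":
            nxa[c[1]] += post[i]
        elif c[2] == "G":
            nxg[c[1]] += post[i]
    nxa_nxg = {
        b: (nxa[b] / nxg[b]) if nxg[b] > 0 else math.nan for b in "ACGT"
    }

    p_t = sum(post[i] for i, c in enumerate(ALL_CODONS) if c[2] == "T")
    p_c = sum(post[i] for i, c in enumerate(ALL_CODONS) if c[2] == "C")
    p_start_g = sum(post[i] for i, c in enumerate(ALL_CODONS) if c[0] == "G")
    base_ratio = p_t / p_c if p_c > 0 else math.nan
    ntx_ncx = {b: base_ratio for b in "ACT"}
    if p_c > 0 and config.m_sense < 1:
        ntx_ncx["G"] = (p_t + config.m_sense * p_c) / ((1 - config.m_sense) * p_c)
    else:
        ntx_ncx["G"] = math.nan

    flux = p_c * config.m_sense * p_start_g
    sc_mask = np.array([c in SC_SET for c in ALL_CODONS])
    ending = {b: 0.0 for b in "ACGT"}
    for i, c in enumerate(ALL_CODONS):
        if sc_mask[i]:
            ending[c[2]] += post[i]
    ending["C"] -= flux
    ending["T"] += flux
    sc_mass = sum(ending.values())
    ending = {b: v / sc_mass for b, v in ending.items()}
    at = ending["A"] + ending["T"]
    cg = ending["C"] + ending["G"]
    return ExpectedRatios(
        nxa_nxg=nxa_nxg,
        ntx_ncx=ntx_ncx,
        ending_freq=ending,
        at_cg_ratio=at / cg if cg > 0 else math.nan,
    )


def recover_conversion_rate(
    observed: SecondPositionTable, config: SimulationConfig
) -> float:
    """Moment estimator of the antisense conversion rate m_anti.

    Inverts E[NCA/NCG] = (R0 + m) / (1 - m), where R0 is the baseline
    NCA/NCG ratio implied by the config at m_anti = 0, giving
    m_hat = (R_obs - R0) / (1 + R_obs). Clamped to 0 with a warning when
    the observed ratio falls below baseline.
    """
    if observed.nxg["C"] == 0:
        raise ValueError("observed NCG count is zero; ratio undefined")
    r_obs = observed.nxa["C"] / observed.nxg["C"]
    baseline = expected_ratios(replace(config, m_anti=0.0))
    r0 = baseline.nxa_nxg["C"]
    m_hat = (r_obs - r0) / (1.0 + r_obs)
    if m_hat < 0:
        warnings.warn(
            f"observed NCA/NCG ratio {r_obs:.4f} below baseline {r0:.4f}; "
            "clamping recovered rate to 0"
        )
        return 0.0
    return min(m_hat, 1.0)
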