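# Methods

## Scope and model of the data

The package analyzes synonymous codon usage bias (SCUB) from a genome
assembly (FASTA) plus gene annotation (GFF3). The unit of observation is
one coding sequence per gene: the first transcript in file order (ties
broken by lexicographic transcript id, which can only arise in
constructed inputs). CDS segments are concatenated 5'→3', minus-strand
segments reverse-complemented. Four acceptance rules follow standard
codon-usage practice: length divisible by 3, no ambiguous base (any
non-ACGT IUPAC letter rejects, with the letter recorded), ATG start,
TAA/TAG/TGA final codon. The GFF3 phase column is ignored — frame
correctness is enforced post hoc by these filters. Internal stop codons
do not reject a gene; they are simply counted as stops and therefore sit
outside the 59-SC universe used by every downstream statistic. Genes
whose transcript has more than `max_exons` (default 10) CDS-bearing exons
enter genome-wide statistics but not the exon strata; exon count means
CDS-bearing exons, since UTR-only exons are invisible to codon data.

Every codon of an accepted CDS belongs to exactly one exon. The split
rule is implemented as "the exon containing the codon's second
nucleotide", which reproduces both halves of the convention — a codon
interrupted after its first nucleotide belongs to the downstream exon,
after its second to the upstream exon — and resolves the degenerate case
of a codon spanning three exons to the middle one.

## Codon statistics

All SCUB quantities use the 59 SCs (61 sense codons minus ATG and TGG).
"Omitting the start codon" is read as omitting all ATG codons, not only
the initial one, since methionine has no synonyms and a per-position
exception would make the SC universe inconsistent between statistics.

* Ending frequencies are counts of A/T/C/G-ending SCs over the SC total;
  they sum to 1 by construction. The NNA/T : NNC/G ratio derives from
  their pooled forms.
* RSCU_c = count_c / (family_total / family_size). Families with zero
  total yield NaN, never 0 — undefined ratios propagate as NaN
  everywhere in the package because silently zeroed values would bias
  CVs and tests downstream.
* CAI uses relative adaptiveness w_c = RSCU_c / max(RSCU in family) from
  a reference count table. No expression data is assumed: the default
  reference is the whole-genome table, and a gene-list option supports a
  "highly expressed" reference when one exists. A codon unobserved in an
  otherwise observed family receives a floor weight of 0.01
  (configurable) so the geometric mean never hits log 0; entirely
  unobserved families are skipped and reflected in `codons_used`.
* ENC is Wright's statistic with per-family
  F = (n Σp² − 1)/(n − 1), class means over the 2-, 3-, 4- and 6-fold
  degeneracy classes, and the conventional cap at 61 (the unbiased F
  estimator falls slightly below 1/k at finite counts, which would
  otherwise push no-bias tables above 61). A degeneracy class with no
  defined family borrows the mean F of all defined families.

## Deamination contexts

Methylated cytosine deaminates to thymine. Two sequence contexts carry
the footprint inside coding sequence without changing the protein:
NCG → NCA (CpG on the antisense strand read through the codon's second
and third position) and NC|G → NT|G (CpG on the sense strand across a
codon junction). Both are always synonymous in the standard code. The
module therefore tallies A- vs G-ending SCs by second base (NXA, NXG)
and junction pairs by the upstream codon's final T/C and the downstream
codon's first base (NT|X, NC|X). Junction pairs require the upstream
codon to be an SC ending T or C and the downstream codon to be non-stop,
keeping both statistics inside the SC universe; junctions are within-CDS
only (introns are spliced out), and a junction straddling an exon
boundary is attributed to the upstream codon's exon for stratified
tables.

## Comparative statistics

Chi-square tests are Pearson, no continuity correction. "Partitioning"
an m × k table means testing every 2 × k sub-table; the compact letter
display is built from the pairwise significance graph by insert-and-
absorb with groups processed in label order, so letters are a
deterministic function of the p-matrix and alpha. No multiplicity
correction is applied by default — matching the single-alpha letters
conventionally reported with partitioned chi-square — with a Bonferroni
switch available. The t-test is Welch's (the safer default when the
variant is unspecified); CV is sample SD over mean.

## Ordination

Entities are clustered by UPGMA over Euclidean distances on 59-SC
feature vectors, with merge heights also expressible as percent
similarity, 100·(1 − d/d_max). PCA eigendecomposes the correlation
matrix by default: a scale-free choice that stands in for opaque
statistical-software defaults. Factor score coefficients are
eigenvectors scaled by λ^−1/2 (components with λ ≤ 1e−12 are dropped
from that scaling), and each component's sign is fixed so its
largest-magnitude loading is positive, making outputs stable across
linear-algebra backends.

## The synthetic-data generator

The generator targets the statistical structure the analysis measures,
not wheat realism: gene models are ATG + L drawn codons + stop, split
into e exons by e−1 intron insertion points drawn uniformly over
inter-nucleotide positions (so both 1|2 and 2|3 codon splits arise
naturally), placed on named chromosomes with random strand and
intergenic spacers. Codons are drawn per amino acid (default uniform
composition over the 20) from within-family distributions where
C/G-ending codons carry odds `cg_odds` (default 1.5, giving a wheat-like
NNA/T : NNC/G ratio below 1) and interior-exon codons have their
A/T-ending odds multiplied by `interior_tilt`. Deamination is then
applied: each NCG flips to NCA with probability `m_anti`, and each
C-ending codon followed by a G-starting codon flips to its T-ending
synonym with probability `m_sense`. Synonymy of every conversion is
asserted at run time by translating pre- and post-conversion sequences.
Defaults: 200 genes, 100–300 internal codons, exon counts uniform on
1..10, introns 60–200 nt, 100 nt spacers, both rates 0.

Randomness is a per-gene substream keyed by (seed, gene index), so
output is byte-identical for a config and enlarging `n_genes` never
reshuffles earlier genes.

Closed-form expectations accompany the generator: per draw,
E[NCA] = p_NCA + m_anti·p_NCG and E[NCG] = (1 − m_anti)·p_NCG, so
E[NCA/NCG] = (R₀ + m)/(1 − m) with R₀ the baseline ratio; inverting
gives the moment estimator m̂ = (R_obs − R₀)/(1 + R_obs), clamped to 0
with a warning when the observed ratio falls below baseline. For
junction ratios the downstream-start factor cancels, so only NT|G/NC|G
moves with m_sense: (p_T + m_sense·p_C)/((1 − m_sense)·p_C). The
expectations use the baseline (terminal-exon) codon distribution; with
`interior_tilt` ≠ 1 the genome-wide mixture shifts p_NCA upward, so rate
recovery is exact only against the matching baseline — visible as a
positive bias if a tilted genome is inverted with a no-tilt baseline.

What the generator does not emulate: real gene-length and GC landscapes,
splice-site motifs, isoform structure, expression-correlated usage, or
selection. Passing tests therefore demonstrate correctness of the
counting, stratification and inference machinery under known structure,
not biological conclusions about real genomes.

## Problem sizes and numerical choices

The test and acceptance workloads are sized for quick desk-scale runs:
oracle equivalence uses 20 seeded 200-gene genomes checked cell-exactly
against direct recounts of the generator's truth; rate recovery uses
2×10⁵ SC draws × 20 replicates per level over m_anti ∈ {0, 0.2, 0.4}
(draw counts are inflated by the inverse SC mass of the distribution so
the SC draw count hits the target); positional structure uses 300-gene
genomes with exon counts on 3..8 and tilt 1.5, with the no-tilt null
checked by Kolmogorov–Smirnov uniformity of chi-square p-values over 10
replicate genomes; "unchanged at baseline" contexts are tested with
Welch t-tests at alpha = 0.01 against the zero-rate replicates. Display
rounding (3 decimals) happens only at the writer layer; computation
keeps full precision. TSV output uses a fixed float format so reruns on
identical inputs are byte-identical.

## Known limitations

- "Chi-square partitioning" schemes vary across the literature; the
  all-pairwise sub-table reading implemented here is the common one, but
  letters from other partitioning schemes need not coincide.
- The CAI reference defaults to the whole-genome table; absolute CAI
  values are therefore not comparable with CodonW runs configured with
  an expression-based reference set, although rankings are.
- GTF and trans-splicing are unsupported; gene-level CDS without mRNA
  features is handled as a single transcript.
- The ortholog step consumes a precomputed table (group_id,
  species_label, gene_id); collinearity/BLAST detection is external.
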