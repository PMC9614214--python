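import pytest

from scubkit import genome_io
from scubkit import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome(tmp_path_factory):
    """One simulated species with both conversions on, written to disk."""
    config = sd.SimulationConfig(
        seed=11,
        n_genes=40,
        codons_min=40,
        codons_max=100,
        m_anti=0.15,
        m_sense=0.2,
        chromosomes=("chr1A", "chr3B", "chr5D", "scaffold_7"),
        exon_count_probs={e: 1.0 for e in range(1, 13)},
    )
    genome = sd.simulate_genome(config)
    directory = tmp_path_factory.mktemp("sim")
    fasta, gff3 = genome.write(directory)
    return genome, fasta, gff3


@pytest.fixture(scope="session")
def extracted(small_genome):
    """The same genome pushed through FASTA/GFF3 extraction."""
    genome, fasta, gff3 = small_genome
    records = genome_io.extract_cds_records(fasta, gff3, species_label="sim")
    return genome, records
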