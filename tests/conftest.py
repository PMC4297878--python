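import pytest

from ampscan.genome import GeneRecord, GenomeAnnotation
from ampscan.simulate import SimulationConfig, simulate_genome, simulate_ground_truth


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A light-weight cohort: 300 genes on 20 Mb, modest read depth."""
    return SimulationConfig(
        chrom_sizes={"chr1": 20_000_000},
        n_genes=300,
        seed=11,
        chip_reads_per_factor=30_000,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate_genome(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_annotation):
    return simulate_ground_truth(small_annotation, small_config)


@pytest.fixture
def toy_annotation():
    """Three hand-placed genes (two strands, one near the chromosome edge)."""
    sizes = {"chr1": 100_000}
    records = [
        GeneRecord("gA", "chr1", 10_000, 20_000, "+"),
        GeneRecord("gB", "chr1", 40_000, 50_000, "-"),
        GeneRecord("gC", "chr1", 3_000, 6_000, "+"),
    ]
    return GenomeAnnotation(records, sizes)
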