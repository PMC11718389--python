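import hypothesis
import pytest

from oligobar import SimulationSpec, simulate_genome

hypothesis.settings.register_profile(
    "repro", derandomize=True, max_examples=40, deadline=None
)
hypothesis.settings.load_profile("repro")


@pytest.fixture(scope="session")
def diploid_two_chrom_genome():
    """Two chromosomes, two homologous copies each, modest SNP divergence."""
    spec = SimulationSpec(
        n_chromosomes=2,
        chromosome_lengths=(12_000, 12_000),
        ploidy=2,
        snp_rate=1e-3,
        rng_seed=7,
    )
    genome, ledger = simulate_genome(spec)
    return genome, ledger


@pytest.fixture(scope="session")
def tetraploid_genome():
    """One chromosome group with four identical-descended copies."""
    spec = SimulationSpec(
        n_chromosomes=1,
        chromosome_lengths=(20_000,),
        ploidy=4,
        snp_rate=5e-4,
        rng_seed=11,
    )
    genome, ledger = simulate_genome(spec)
    return genome, ledger
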