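import pytest

from graftscope.synthetic_data import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """One-chromosome simulation shared across tests (cheap, seeded)."""
    cfg = SimulationConfig(
        seed=7, n_chromosomes=1, chrom_length=60_000, n_genes_per_chrom=12
    )
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """Full default-scale simulation for the recovery acceptance checks."""
    return simulate_all(SimulationConfig(seed=11))
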