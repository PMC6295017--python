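import pytest

from plasticipan.forge import EvolutionConfig, evolve_collection


@pytest.fixture(scope="session")
def planted_collection():
    """Default two-group collection with known truth (shared, read-only).

    10 genomes, 200 core + 100 accessory + 8/3 group-exclusive families,
    5 core families carrying a paralog so that the strict single-copy set
    is a proper subset of the core.
    """
    cfg = EvolutionConfig(seed=0, paralog_families=5)
    genomes, proteins, truth = evolve_collection(cfg)
    return cfg, genomes, proteins, truth


@pytest.fixture(scope="session")
def divergent_pair():
    """Two 100-kb genomes at 8% per-site divergence, 5 rearrangements."""
    cfg = EvolutionConfig(
        n_genomes=2, group_sizes=(1, 1), substitution_rate=0.08,
        n_rearrangements=5, core_size=5, accessory_pool=0,
        group_specific_counts=(0, 0), seed=2,
    )
    return evolve_collection(cfg)
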