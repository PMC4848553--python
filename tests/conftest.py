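import numpy as np
import pytest

from radscreen import CohortConfig, LineageSpec, PlantedEffect, simulate_cohort
from radscreen.simulate import GenomeModel


@pytest.fixture(scope="session")
def small_genome():
    return GenomeModel.default(n_chromosomes=10, chromosome_length=100_000,
                               genes_per_chromosome=5, gene_length=2_000)


@pytest.fixture(scope="session")
def planted_cohort(small_genome):
    """100-line cohort with one planted resistance mutation and nulls."""
    config = CohortConfig(
        lineages=(LineageSpec("LUAD", 60, 3.5, 0.8), LineageSpec("BREAST", 40, 3.0, 0.8)),
        planted_features=(
            PlantedEffect("KEAP1L", "mutation", prevalence=0.2, effect_size=2.0,
                          linked_genes=("G0001", "G0002", "G0003", "G0004", "G0005",
                                        "G0006", "G0007")),
        ),
        n_null_features=30,
        noise_cv=0.05,
        seed=42,
        genome=small_genome,
    )
    return simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
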