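import numpy as np
import pytest

from epibayes import GenomeMap, breed_structured_generations, simulate_base_population


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """A cheap linked population (200 markers, Ne=40) for structural tests."""
    rng = np.random.default_rng(99)
    genome = GenomeMap.uniform_random(200, rng, n_chromosomes=5)
    base = simulate_base_population(genome, 40, 2.5e-3, 60, rng)
    return breed_structured_generations(base, n_families=8, n_offspring_per_family=5,
                                        n_train_generations=2, n_test_generations=2,
                                        rng=rng, mutation_rate=2.5e-3)
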