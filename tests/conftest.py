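import numpy as np
import pandas as pd
import pytest

from envqtl import CrossDesign, simulate_genotypes


@pytest.fixture(scope="session")
def small_genotypes():
    """50 segregants x 20 unlinked markers."""
    design = CrossDesign(
        n_segregants=50,
        chromosomes=(("chrA", 100_000),),
        markers_per_chromosome=20,
        recomb_prob=0.5,
        seed=3,
    )
    return simulate_genotypes(design)


@pytest.fixture(scope="session")
def linked_genotypes():
    """200 segregants x 100 linked markers on 2 chromosomes."""
    design = CrossDesign(
        n_segregants=200,
        chromosomes=(("chrA", 500_000), ("chrB", 500_000)),
        markers_per_chromosome=50,
        recomb_prob=0.05,
        seed=7,
    )
    return simulate_genotypes(design)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
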