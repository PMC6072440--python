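import numpy as np
import pytest

from crossqtl import synth


@pytest.fixture(scope="session")
def small_cross():
    """A 300-segregant, 4-chromosome cross shared across tests."""
    design = synth.default_design(n_segregants=300, n_chromosomes=4,
                                  markers_per_chrom=40, seed=11)
    return synth.simulate_cross(design)


@pytest.fixture(scope="session")
def planted_study(small_cross):
    """Cross plus planted expression with known truth (30 genes)."""
    rng = np.random.default_rng(23)
    truth = synth.make_truth(small_cross, 30, rng, mean_eqtls_per_gene=2)
    expr, cov = synth.plant_expression(small_cross, truth, rng)
    return small_cross, truth, expr, cov


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
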