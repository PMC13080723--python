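import numpy as np
import pytest

from chromsig import SimulationConfig, simulate_atac_experiment, simulate_reference


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down study design for fast unit tests."""
    return SimulationConfig(
        seed=11,
        n_genes=300,
        effector_gene_count=30,
        memory_gene_count=30,
        n_intergenic_peaks=100,
        cells_per_state=150,
    )


@pytest.fixture(scope="session")
def atac_fixture(small_cfg):
    """(peaks, genes, counts, samples, truth) from the small design."""
    return simulate_atac_experiment(small_cfg)


@pytest.fixture(scope="session")
def ref_fixture(small_cfg):
    """(reference expression, truth) from the small design."""
    return simulate_reference(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
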