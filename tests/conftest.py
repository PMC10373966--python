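import numpy as np
import pytest

from epoch import sim_counts, sim_images


@pytest.fixture(scope="session")
def small_field():
    """A quiet 20-cell field with moderate mislocalization."""
    cfg = sim_images.SimImageConfig(mislocalization_fraction=0.2, seed=3)
    return sim_images.simulate_ncc_field(cfg)


@pytest.fixture(scope="session")
def noiseless_healthy_field():
    """Single healthy cell, zero noise: mCherry strictly nuclear."""
    cfg = sim_images.SimImageConfig(
        n_cells=1,
        height=96,
        width=96,
        mislocalization_fraction=0.0,
        noise_sd=0.0,
        background_level=0.0,
        seed=1,
    )
    return sim_images.simulate_ncc_field(cfg)


@pytest.fixture(scope="session")
def two_group_matrix():
    """Quiescent vs senescent experiment with a planted signature."""
    cfg = sim_counts.SimCountConfig(
        n_genes=1500,
        samples_per_group=4,
        senescence_log2fc=2.5,
        seed=7,
    )
    return sim_counts.simulate_counts(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
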