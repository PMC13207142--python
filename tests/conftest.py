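import numpy as np
import pandas as pd
import pytest

from sexstrat.simulate import SimulationConfig, generate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A small three-study compendium with planted effects (shared fixture)."""
    cfg = SimulationConfig(n_genes=600, n_shared_degs=40,
                           n_female_unique_degs=10, n_male_unique_degs=10,
                           n_interaction_genes=6, seed=7)
    counts, meta, truth = generate_counts(cfg)
    return cfg, counts, meta, truth


@pytest.fixture()
def tiny_counts():
    """3 genes x 2 samples with unequal libraries."""
    return pd.DataFrame([[10, 20], [0, 5], [30, 15]],
                        index=["g1", "g2", "g3"], columns=["s1", "s2"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
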