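import numpy as np
import pytest

from pgxagree import SimulationParams, generate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_params():
    """Scaled-down generator parameters for fast unit tests."""
    return SimulationParams(n_cell_lines=60, n_drugs=5, n_genes=12,
                            n_causal_pairs=6, seed=17)


@pytest.fixture
def small_pair(small_params):
    return generate_pair(small_params)


@pytest.fixture
def aligned_pair(small_pair):
    return small_pair.paired_study()
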