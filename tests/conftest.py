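import numpy as np
import pytest

from prognet import synthetic as syn


@pytest.fixture(scope="session")
def small_bundle():
    """A compact deterministic cohort used across test modules."""
    cfg = syn.SimConfig(n_samples=300, n_genes=40, seed=5)
    return syn.assemble_cohort(cfg)


@pytest.fixture(scope="session")
def small_interactome(small_bundle):
    return syn.simulate_interactome(list(small_bundle.expression.index),
                                    small_bundle.truth,
                                    n_background_edges=60, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
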