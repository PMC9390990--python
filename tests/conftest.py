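import numpy as np
import pytest

import beliefnet as bn


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_truth():
    """K=6, two clusters, 4 waves with the default interdependence profile."""
    return bn.make_ground_truth(K=6, sparsity=0.4, waves=4, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_truth):
    """Raw-dialect Likert panel from the GGM sampler."""
    return bn.simulate_panel_ggm(small_truth, n=60, seed=12, groups=["control", "g1"])


@pytest.fixture(scope="session")
def rescaled_panel(small_panel):
    return bn.rescale_beliefs(small_panel)
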