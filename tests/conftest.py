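import numpy as np
import pytest

from hipposim import ca3, patterns


@pytest.fixture(scope="session")
def small_net():
    """A small stored attractor well below capacity: (graph, ensemble, weights)."""
    n, c, a, p = 500, 100, 0.05, 5
    graph = ca3.build_connectivity(n, c, seed=11)
    ens = patterns.generate_binary_ensemble(n, p, a, seed=12)
    w = ca3.store_auto(ens, graph, ca3.LearningRule(a_prior=a))
    return graph, ens, w


@pytest.fixture
def rng():
    return np.random.default_rng(123)
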