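import numpy as np
import pytest

import rlctrnn as r


@pytest.fixture(scope="session")
def oscillator():
    """The committed evolved two-neuron oscillator."""
    return r.load_evolved_oscillator()


@pytest.fixture(scope="session")
def perturbed_start(oscillator):
    """Common starting configuration: the oscillator displaced by Euclidean
    distance 8 in weight space (a feasible direction given the saturated
    weights)."""
    return r.perturb_weights(
        oscillator, r.PerturbationSpec(magnitude=8.0, mode="exact-distance"), seed=0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_network(n, seed=0, scale=4.0):
    """Small random network with interior (non-saturated) parameters."""
    g = np.random.default_rng(seed)
    return r.NetworkParameters(
        weights=g.uniform(-scale, scale, size=(n, n)),
        biases=g.uniform(-scale, scale, size=n),
        time_constants=np.ones(n),
    )
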