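import numpy as np
import pytest

from spikebench.network import (
    Connection,
    Connector,
    NetworkDescription,
    NeuronParameters,
    Population,
)


@pytest.fixture
def self_firing_params():
    # resting potential above threshold: fires by itself, refractory-limited
    return NeuronParameters(
        v_rest=-40.0, v_thresh=-60.0, v_reset=-61.0, tau_m=1.0, tau_refrac=1.0
    )


@pytest.fixture
def single_neuron_net(self_firing_params):
    return NetworkDescription().add(
        Population("n", 1, "lif_current", self_firing_params)
    )


@pytest.fixture
def driven_pair_net():
    """Array source -> one LIF neuron, strong enough to force a spike."""
    params = NeuronParameters(tau_refrac=2.0, tau_m=5.0, tau_syn_exc=2.0, c_m=0.25)
    return NetworkDescription().add(
        Population("src", 1, "source_array", {"spike_times": [5.0, 30.0]}),
        Population("n", 1, "lif_current", params),
        Connection("src", "n", Connector.one_to_one(), 6.0),
    )
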