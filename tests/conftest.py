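import dataclasses

import numpy as np
import pytest

from stresswm import (CapacityCriterion, Connectivity, NetworkConfig,
                      StimulusProtocol, SynapseParams)


@pytest.fixture
def tiny_network_config():
    """A desk-scale network: 4 groups of (8E, 2I), fully deterministic."""
    return NetworkConfig(n_groups=4, n_exc_per_group=8, n_inh_per_group=2)


@pytest.fixture
def short_protocol():
    """A compressed recall protocol for fast engine tests."""
    return StimulusProtocol(t_fixation=100.0, t_memory=80.0, t_delay=120.0,
                            t_cue=5.0, t_post=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
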