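import numpy as np
import pytest

from spiralscope.spikes import SpikeData
from spiralscope.synth import LatentSpiralParams, generate_spiral_population


@pytest.fixture(scope="session")
def small_population():
    """A reduced synthetic program (40 neurons, 30 s evoked) for unit tests."""
    params = LatentSpiralParams(
        n_neurons=40, pre_s=10.0, post_s=30.0, transient=5.0, seed=123
    )
    spikes, truth = generate_spiral_population(params)
    return spikes, truth


@pytest.fixture(scope="session")
def default_population():
    """One full-size synthetic program under the default study conditions."""
    spikes, truth = generate_spiral_population(LatentSpiralParams(seed=7))
    return spikes, truth


@pytest.fixture()
def regular_train():
    """A 1 Hz regular spike train over 100 s wrapped as SpikeData."""
    times = np.arange(0.5, 100.0, 1.0)
    return SpikeData(spikes=[times], duration=100.0, stim_on=0.0, stim_off=0.0)
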