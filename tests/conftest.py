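import numpy as np
import pytest

from confinequant import ChannelSpec, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_config(**overrides) -> SimulationConfig:
    """Small, fast movie configuration for tests (short channel, few frames)."""
    defaults = dict(
        n_frames=40,
        channel_spec=ChannelSpec(10.0, 3.0, 80.0),
        noise_model=(0.0, 0.0, 0.0),
        rupture_schedule=[],
        ace_schedule=[],
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def config_factory():
    return make_config
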