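import numpy as np
import pytest

from gradedbci.synthetic import ChannelTuningProfile, N_CHANNELS, assign_profiles
from gradedbci.task_design import BlockSpec, VIRTUAL_ANGLES, make_block


@pytest.fixture(scope="session")
def default_profiles():
    return assign_profiles(56, seed=0)


@pytest.fixture(scope="session")
def flat_profiles():
    return [
        ChannelTuningProfile(channel_id=i + 1, klass="flat", gain=0.0)
        for i in range(N_CHANNELS)
    ]


@pytest.fixture(scope="session")
def one_increasing_profiles():
    profs = [
        ChannelTuningProfile(channel_id=i + 1, klass="flat", gain=0.0)
        for i in range(N_CHANNELS)
    ]
    profs[0] = ChannelTuningProfile(
        channel_id=1, klass="increasing", gain=2.0, latency_s=0.3
    )
    return profs


@pytest.fixture()
def virtual_block_cues():
    spec = BlockSpec(1, "open_loop", VIRTUAL_ANGLES, 0.0, seed=11)
    return make_block(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
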