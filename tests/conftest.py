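import numpy as np
import pytest
from hypothesis import settings

from blastsleep import SimConfig
from blastsleep.signal_io import Hypnogram

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def short_record(sim_cfg):
    """A 12-min default-contrast record with ground truth (seed 1)."""
    from blastsleep.synthetic import simulate_record

    return simulate_record(sim_cfg, 1, duration_h=0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_hypnogram(labels, epoch_len_s=5.0, t0="09:00"):
    return Hypnogram(labels=np.asarray(labels), epoch_len_s=epoch_len_s, t0=t0)
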