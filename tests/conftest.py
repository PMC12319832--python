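import numpy as np
import pytest

from mmnflow import hgf, paradigm, synthetic


@pytest.fixture(scope="session")
def layout16():
    return synthetic.SensorLayout.standard_1020(16)


@pytest.fixture(scope="session")
def layout64():
    return synthetic.SensorLayout.standard_1020(64)


@pytest.fixture(scope="session")
def template_sequence():
    sched = paradigm.default_schedule(600)
    seq = paradigm.sample_sequence(sched, seed=123)
    return sched, seq


@pytest.fixture(scope="session")
def short_trajectories():
    u = (np.arange(80) % 3 == 0).astype(np.int8)
    return hgf.filter_sequence(u)
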