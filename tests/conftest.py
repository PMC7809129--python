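import numpy as np
import pytest

from shankgait import GaitSimConfig, reconstruct, simulate_walk


@pytest.fixture(scope="session")
def default_cfg():
    return GaitSimConfig(n_strides=10, stride_length_m=1.2, stride_duration_s=1.1)


@pytest.fixture(scope="session")
def noiseless_trial(default_cfg):
    return simulate_walk(default_cfg)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_trial, default_cfg):
    return reconstruct(noiseless_trial.rec, r=default_cfg.r_m, method="ipm")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
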