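import numpy as np
import pytest

from drydown import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_truth():
    """Short linear-ramp drydown with a P. cembra-like threshold distribution."""
    return syn.DrydownTruth.linear_ramp(weibull_scale=3.54, weibull_shape=5.86,
                                        seed=7, psi_end=-7.0, duration_s=7200.0)


@pytest.fixture
def small_config():
    return syn.SyntheticConfig(n_conduits=60, region_um=(250.0, 250.0),
                               min_separation_um=2.0,
                               psi_sample_interval_s=900.0)
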