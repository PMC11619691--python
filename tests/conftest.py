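import numpy as np
import pytest

from hcquant.synthdata import GroundTruth, SynthConfig


@pytest.fixture
def clean_config():
    """Noise-free acquisition config for exact-recovery tests."""
    return SynthConfig(n_rois=3, noise_sd=0.0, oscillation_rate=0.0)


@pytest.fixture
def clean_truth():
    """Ground truth with bleaching disabled, for exact-recovery tests."""
    return GroundTruth(seed=7, bleach_tau=None)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
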