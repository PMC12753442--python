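import numpy as np
import pytest

from lnmfusion.cohort import SyntheticParams, generate_cohort
from lnmfusion.contrastive import ContrastiveConfig
from lnmfusion.encoders import EncoderConfig
from lnmfusion.training import TrainConfig, split_cohort, train


@pytest.fixture(scope="session")
def small_cohort():
    """40-patient strong-signal cohort at small image scale."""
    params = SyntheticParams(seed=11, n_patients=40, n_positive=6,
                             image_size=32, effect_ct=2.5, effect_us=2.5,
                             effect_clin=2.5)
    return generate_cohort(params)


@pytest.fixture(scope="session")
def test_encoder_config():
    return EncoderConfig(image_input_side=32, backbone="reduced", seed=0)


@pytest.fixture(scope="session")
def smoke_checkpoint(small_cohort, test_encoder_config):
    """A short real training run shared by the contract tests."""
    split = split_cohort(small_cohort, seed=0)
    ckpt = train(small_cohort, split, TrainConfig(epochs=2, seed=0),
                 test_encoder_config, ContrastiveConfig())
    return ckpt, split


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
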