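import numpy as np
import pytest

from pulsechase import default_config


@pytest.fixture(scope="session")
def cfg():
    """The committed default study configuration."""
    return default_config()


@pytest.fixture(scope="session")
def noiseless_cfg(cfg):
    return cfg.with_(noise_sd_delta=0.0, assay_noise_cv=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
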