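from pathlib import Path

import numpy as np
import pytest

CONFIG_DIR = Path(__file__).resolve().parents[1] / "configs"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config_dir():
    return CONFIG_DIR
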