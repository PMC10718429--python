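import numpy as np
import pytest

from sharpseg import generate_dataset


@pytest.fixture(scope="session")
def phantom_root(tmp_path_factory):
    """Small BUSI-layout phantom tree shared by I/O and pipeline tests."""
    root = tmp_path_factory.mktemp("phantoms")
    generate_dataset((3, 5, 4), root, base_seed=11)
    return root


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
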