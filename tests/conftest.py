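import numpy as np
import pytest

from awpfnet.data import DatasetSpec, generate_synthetic_dataset


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The full default synthetic dataset (2,435 images), generated once."""
    root = tmp_path_factory.mktemp("default_synth")
    ds = generate_synthetic_dataset(DatasetSpec(), root)
    return root, ds


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small 7-class set at 64x64 for fast training-path tests."""
    root = tmp_path_factory.mktemp("tiny_synth")
    spec = DatasetSpec(image_size=(64, 64)).scaled(0.02, min_train=3, min_val=2)
    ds = generate_synthetic_dataset(spec, root)
    return root, ds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
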