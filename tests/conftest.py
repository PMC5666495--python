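import numpy as np
import pytest

from nanoqsar.dataset_io import load_atomic_masses, load_dataset, load_ion_table


@pytest.fixture(scope="session")
def dataset():
    return load_dataset("builtin")


@pytest.fixture(scope="session")
def masses():
    return load_atomic_masses("builtin")


@pytest.fixture(scope="session")
def ion_table():
    return load_ion_table("builtin")


@pytest.fixture(scope="session")
def train_frame(dataset):
    frame = dataset.to_frame()
    return frame[frame["subset"] == "train"]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
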