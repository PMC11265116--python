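import numpy as np
import pytest

from mvselect.data import MultiViewDataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_dataset(rng):
    """Two small aligned views with labels."""
    n = 12
    views = [rng.normal(size=(n, 6)), rng.normal(size=(n, 4))]
    names = [[f"a{j}" for j in range(6)], [f"b{j}" for j in range(4)]]
    ids = [f"s{i}" for i in range(n)]
    labels = np.array([1, 2] * 6)
    return MultiViewDataset(views, ids, names, labels)
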