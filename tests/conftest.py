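import numpy as np
import pytest

from edafs import (
    Dataset,
    EpistasisSpec,
    generate_epistasis_dataset,
    make_toy_classification,
    normalize_minmax,
)


@pytest.fixture
def small_ds():
    rng = np.random.default_rng(0)
    X = rng.uniform(0, 1, size=(20, 3))
    y = np.array(["a", "b"] * 10, dtype=object)
    return Dataset(X, y, ["f0", "f1", "f2"])


@pytest.fixture(scope="session")
def xor2_ds():
    return make_toy_classification("xor2", m=400, n_noise=3, seed=11)


@pytest.fixture(scope="session")
def parity3_ds():
    spec = EpistasisSpec(k=3, n_noise=5, m=600, seed=42)
    return normalize_minmax(generate_epistasis_dataset(spec))
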