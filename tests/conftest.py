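import numpy as np
import pandas as pd
import pytest

from snakeswarm.prep import ColumnSchema, TabularDataset
from snakeswarm.swarm import BoundsSpec, OptimizerConfig


@pytest.fixture
def sphere():
    return lambda x: float(np.sum(np.square(x)))


@pytest.fixture
def box10():
    return BoundsSpec.cube(-5.0, 5.0, 10)


@pytest.fixture
def small_config():
    return OptimizerConfig(n_pop=10, n_iter=20, seed=0)


def make_dataset(X, y, kinds=None):
    """Assemble a TabularDataset from arrays; kinds maps column -> kind."""
    X = pd.DataFrame(X)
    X.columns = [str(c) for c in X.columns]
    kinds = kinds or {}
    schema = [ColumnSchema(c, kinds.get(c, "numeric")) for c in X.columns]
    schema.append(ColumnSchema("class", "label"))
    return TabularDataset(X, pd.Series(y, name="class"), schema)


@pytest.fixture
def two_class_imbalanced():
    """1000-vs-100 Gaussian blobs, linearly separated but overlapping."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 1.0, size=(1000, 4))
    b = rng.normal(2.0, 1.0, size=(100, 4))
    X = np.vstack([a, b])
    y = np.array([0] * 1000 + [1] * 100)
    return make_dataset(X, y)
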