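import numpy as np
import pytest

from locnet.dataset import LocationVocabulary, MultiLocDataset


@pytest.fixture
def vocab2():
    return LocationVocabulary(("cyt", "nuc"))


@pytest.fixture
def small_dataset(vocab2):
    """Six proteins, two features, a mix of single- and double-localized."""
    X = np.array(
        [[0.5, 1.0], [1.5, 2.0], [2.5, 3.0], [3.5, 4.0], [1.0, 0.0], [3.0, 5.0]]
    )
    Y = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [1, 1], [1, 1]])
    ids = [f"P{i}" for i in range(6)]
    return MultiLocDataset(vocab2, ids, X, Y, ["f1", "f2"])


def random_discrete_dataset(rng, m, d, q, arity=2):
    """Labeled dataset with integer-coded features, >= 1 positive label."""
    X = rng.integers(0, arity, size=(m, d)).astype(float)
    Y = rng.integers(0, 2, size=(m, q))
    fix = Y.sum(axis=1) == 0
    Y[fix, rng.integers(0, q, size=int(fix.sum()))] = 1
    vocab = LocationVocabulary(tuple(f"loc{i}" for i in range(q)))
    return MultiLocDataset(
        vocab, [f"P{i}" for i in range(m)], X, Y, [f"f{i}" for i in range(d)]
    )
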