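import numpy as np
import pytest

from ddifuse.model import DrugFeatures
from ddifuse.synthetic import gen_world


@pytest.fixture(scope="session")
def small_world():
    """A compact planted world shared by protocol-level tests."""
    return gen_world(n_drugs=60, n_communities=3, p_in=0.3, p_out=0.03,
                     n_types=2, receptors_per_type=20, seed=42)


@pytest.fixture(scope="session")
def default_world():
    """The default study conditions (200 drugs, 4 communities)."""
    return gen_world(seed=0)


@pytest.fixture
def toy_features():
    """Small random frozen channels for classifier unit tests."""
    rng = np.random.default_rng(5)
    n = 24
    return DrugFeatures(
        drugs=[f"D{i:02d}" for i in range(n)],
        chem=rng.random((n, 12, 8)),
        net=rng.random((n, 8)),
        bio=rng.random((n, n)),
    )


@pytest.fixture
def toy_pairs(toy_features):
    """Balanced labelled pairs with a simple planted rule (same parity)."""
    rng = np.random.default_rng(6)
    n = toy_features.n_drugs
    pairs, labels = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append((i, j))
            labels.append(1 if (i % 2) == (j % 2) else 0)
    pairs = np.array(pairs)
    labels = np.array(labels, dtype=float)
    keep = rng.permutation(len(pairs))[:160]
    return pairs[keep], labels[keep]
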