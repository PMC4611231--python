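import numpy as np
import pandas as pd
import pytest

from ribotide.containers import CountTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_table():
    """4 samples x 3 features with two clear groups."""
    counts = np.array(
        [
            [10, 2, 0],
            [12, 1, 1],
            [1, 9, 8],
            [0, 11, 7],
        ]
    )
    return CountTable.from_arrays(
        ["s1", "s2", "s3", "s4"], ["f1", "f2", "f3"], counts
    )


@pytest.fixture
def toy_groups():
    return pd.Series({"s1": "X", "s2": "X", "s3": "Y", "s4": "Y"})


def random_count_table(rng, n_samples=6, n_features=12, depth=500):
    """Multinomial table over a random uneven profile (no zero samples)."""
    p = rng.dirichlet(np.ones(n_features))
    counts = np.vstack([rng.multinomial(depth, p) for _ in range(n_samples)])
    # guarantee no all-zero sample
    counts[:, 0] += 1
    ids = [f"s{i}" for i in range(n_samples)]
    feats = [f"f{j}" for j in range(n_features)]
    return CountTable.from_arrays(ids, feats, counts)
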