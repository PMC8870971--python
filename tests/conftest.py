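import numpy as np
import pytest

from cimpute import LabeledMatrix, TransactionDB


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 attributes, one missing cell, two classes."""
    values = np.array([[1.0, 10.0], [2.0, np.nan], [3.0, 30.0]])
    return LabeledMatrix(values, np.array(["a", "b", "a"], dtype=object), ["x", "y"])


@pytest.fixture
def worked_example_db():
    """Three transactions all sharing {1, 4, 13}, with per-transaction extras.

    Realizes the textbook situation in which {1,4} and {4,13} are frequent at
    theta=3 but not closed, because {1,4,13} has the same occurrence set.
    """
    return TransactionDB(
        [{1, 4, 13, 2}, {1, 4, 13, 7}, {1, 4, 13}],
        ids=["s1", "s2", "s3"],
    )


def random_db(rng, max_transactions=10, max_items=8):
    """Small random transaction database for miner fuzzing."""
    n = int(rng.integers(1, max_transactions + 1))
    universe = list(range(1, max_items + 1))
    transactions = []
    for _ in range(n):
        size = int(rng.integers(0, max_items + 1))
        transactions.append(set(rng.choice(universe, size=size, replace=False)))
    return TransactionDB(transactions)
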