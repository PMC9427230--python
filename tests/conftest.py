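from __future__ import annotations

import numpy as np
import pytest

from comomine.datasets import demo_db
from comomine.transactions_io import TransactionDB


@pytest.fixture
def demo() -> TransactionDB:
    """The 9-transaction worked-example database over a1..a5."""
    return demo_db()


def random_db(rng: np.random.Generator, max_items: int = 12, max_transactions: int = 40) -> TransactionDB:
    """A small random database for oracle cross-checks."""
    n_items = int(rng.integers(2, max_items + 1))
    n_trans = int(rng.integers(1, max_transactions + 1))
    labels = [f"i{j:02d}" for j in range(n_items)]
    rows = []
    for _ in range(n_trans):
        size = int(rng.integers(1, n_items + 1))
        rows.append(tuple(labels[j] for j in rng.choice(n_items, size=size, replace=False)))
    return TransactionDB.from_itemsets(rows, source_name="random")
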