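"""Length-partitioned Boolean transaction matrices with column-AND counting.

The raw database is scanned once and clustered by transaction cardinality:
all transactions holding exactly ``k`` items form one Boolean matrix of
shape (rows, |universe|), one row per transaction, one column per item.
The support of an itemset within a partition is the sum of the elementwise
AND of its member columns.

Because a k-itemset cannot be contained in a transaction with fewer than
k items, counting starts at the length-k partition and proceeds through
partitions in ascending length, accumulating partial supports.  The scan
terminates early as soon as the running count reaches the support
threshold: the frequency decision is then settled even though the count is
only a lower bound (the ``exact`` flag records this).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from comomine.transactions_io import TransactionDB

__all__ = [
    "PartitionedMatrix",
    "SupportResult",
    "build_partitions",
    "itemset_vector",
    "partition_support",
    "cumulative_support",
    "complete_support",
    "format_partitions",
]


@dataclass(frozen=True)
class PartitionedMatrix:
    """Per-cardinality Boolean matrices over a common item universe.

    ``partitions[k]`` holds every length-k transaction of the source DB as
    a 0/1 row over the full universe, in DB order.  Every row of partition
    k sums to exactly k, and the partition row counts sum to the DB size.
    """

    partitions: dict[int, np.ndarray]
    lengths: tuple[int, ...]
    universe_size: int

    def __post_init__(self) -> None:
        assert self.lengths == tuple(sorted(self.partitions)), "lengths must index partitions"


@dataclass(frozen=True)
class SupportResult:
    """Outcome of an accumulating support scan.

    ``count`` is a lower bound on the true support unless ``exact`` is
    True, in which case every relevant partition was consumed and the
    count is the true support.  ``last_partition_scanned`` is None when no
    partition was visited (e.g. the itemset is longer than any
    transaction).
    """

    itemset: tuple[int, ...]
    count: int
    exact: bool
    last_partition_scanned: int | None


def build_partitions(db: TransactionDB) -> PartitionedMatrix:
    """Cluster the DB into one Boolean matrix per transaction length.

    This is the single pass over the raw transactions that the optimized
    miner performs; all subsequent support counting works on the matrices.
    """
    by_len: dict[int, list[frozenset[int]]] = {}
    for t in db.transactions:
        by_len.setdefault(len(t), []).append(t)
    partitions: dict[int, np.ndarray] = {}
    for k in sorted(by_len):
        rows = by_len[k]
        mat = np.zeros((len(rows), db.n_items), dtype=bool)
        for r, t in enumerate(rows):
            mat[r, sorted(t)] = True
        partitions[k] = mat
    return PartitionedMatrix(
        partitions=partitions, lengths=tuple(sorted(partitions)), universe_size=db.n_items
    )


def _check_itemset(pm: PartitionedMatrix, itemset: Sequence[int]) -> tuple[int, ...]:
    items = tuple(itemset)
    if not items:
        raise ValueError("itemset must be nonempty")
    for i in items:
        if not (0 <= i < pm.universe_size):
            raise KeyError(f"item id {i} outside universe of size {pm.universe_size}")
    return items


def itemset_vector(pm: PartitionedMatrix, length: int, itemset: Sequence[int]) -> np.ndarray:
    """Elementwise AND of the itemset's columns in one partition.

    For a singleton this is the raw column.  Raises KeyError for a length
    with no partition or an item id outside the universe.
    """
    items = _check_itemset(pm, itemset)
    if length not in pm.partitions:
        raise KeyError(f"no partition of length {length}")
    mat = pm.partitions[length]
    return np.logical_and.reduce(mat[:, list(items)], axis=1)


def partition_support(pm: PartitionedMatrix, length: int, itemset: Sequence[int]) -> int:
    """Support of the itemset within a single length partition."""
    return int(itemset_vector(pm, length, itemset).sum())


def cumulative_support(
    pm: PartitionedMatrix,
    itemset: Sequence[int],
    min_supp: int,
    start_length: int | None = None,
) -> SupportResult:
    """Accumulate partition supports in ascending length, stopping early.

    Scanning begins at ``max(start_length, |itemset|)`` (partitions of
    length below the itemset size cannot contribute) and stops as soon as
    the running count reaches ``min_supp``; the count is then a sufficient
    lower bound and ``exact`` is False unless the stop coincided with the
    last partition.  If every partition is consumed the count is the true
    support and ``exact`` is True.
    """
    items = _check_itemset(pm, itemset)
    if min_supp < 1:
        raise ValueError("min_supp must be >= 1")
    lo = max(start_length if start_length is not None else 0, len(items))
    to_scan = [k for k in pm.lengths if k >= lo]
    count = 0
    last: int | None = None
    for idx, k in enumerate(to_scan):
        count += partition_support(pm, k, items)
        last = k
        if count >= min_supp:
            return SupportResult(items, count, exact=(idx == len(to_scan) - 1), last_partition_scanned=last)
    return SupportResult(items, count, exact=True, last_partition_scanned=last)


def complete_support(pm: PartitionedMatrix, result: SupportResult) -> SupportResult:
    """Finish an early-terminated scan so the count becomes exact.

    Rule confidence needs exact supports; this resumes the partition scan
    where :func:`cumulative_support` stopped and consumes the remainder.
    """
    if result.exact:
        return result
    assert result.last_partition_scanned is not None
    count = result.count
    last = result.last_partition_scanned
    for k in pm.lengths:
        if k > result.last_partition_scanned:
            count += partition_support(pm, k, result.itemset)
            last = k
    return SupportResult(result.itemset, count, exact=True, last_partition_scanned=last)


def format_partitions(pm: PartitionedMatrix) -> str:
    """Debug dump: one text block of 0/1 rows per length partition."""
    blocks = []
    for k in pm.lengths:
        rows = ["".join("1" if v else "0" for v in row) for row in pm.partitions[k]]
        blocks.append(f"A(len={k}):\n" + "\n".join(rows))
    return "\n\n".join(blocks)
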