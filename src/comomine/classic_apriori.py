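"""Instrumented level-wise Apriori baseline.

The classic algorithm alternates candidate generation (prefix self-join of
the previous frequent level, then downward-closure pruning) with a full
pass over the raw transactions to count candidate supports — one pass per
level.  ``MiningCounters`` records those passes and the candidate counts
at each generation stage; they are the currency in which the optimized
miner's savings are measured.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from comomine.transactions_io import TransactionDB

__all__ = [
    "ItemsetRecord",
    "FrequentLevel",
    "CandidateSet",
    "MiningCounters",
    "resolve_min_supp",
    "find_frequent_1",
    "self_join",
    "prune_by_subsets",
    "apriori_gen",
    "mine_classic",
]

Itemset = tuple[int, ...]


@dataclass(frozen=True)
class ItemsetRecord:
    """An itemset (sorted ids) with its exact support count."""

    items: Itemset
    support: int


@dataclass(frozen=True)
class FrequentLevel:
    """All frequent itemsets of one size, sorted lexicographically."""

    k: int
    itemsets: tuple[ItemsetRecord, ...]

    def __post_init__(self) -> None:
        for rec in self.itemsets:
            if len(rec.items) != self.k:
                raise ValueError(f"itemset {rec.items} has size != {self.k}")
            if tuple(sorted(rec.items)) != rec.items:
                raise ValueError(f"itemset {rec.items} not sorted")

    def __len__(self) -> int:
        return len(self.itemsets)

    def itemset_tuples(self) -> tuple[Itemset, ...]:
        return tuple(rec.items for rec in self.itemsets)

    def support_of(self, items: Iterable[int]) -> int:
        key = tuple(sorted(items))
        for rec in self.itemsets:
            if rec.items == key:
                return rec.support
        raise KeyError(f"{key} not in level {self.k}")


@dataclass(frozen=True)
class CandidateSet:
    """Size-k candidates pending support verification.

    ``produced_by`` tags the generation stage (``self_join``,
    ``after_preprune`` or ``after_postprune``); ``flagged`` lists
    candidates that miss every constraint item when the optional join
    constraint is active — they are marked, never dropped.
    """

    k: int
    itemsets: tuple[Itemset, ...]
    produced_by: str
    flagged: tuple[Itemset, ...] = ()

    def __post_init__(self) -> None:
        for c in self.itemsets:
            if len(c) != self.k:
                raise ValueError(f"candidate {c} has size != {self.k}")

    def __len__(self) -> int:
        return len(self.itemsets)


@dataclass
class MiningCounters:
    """Efficiency instrumentation shared by both miners.

    ``db_passes`` counts full sweeps over the raw transaction collection
    (the optimized miner makes exactly one — the matrix build).
    ``candidates_per_level`` maps level size to candidate counts at each
    generation stage.
    """

    db_passes: int = 0
    candidates_per_level: dict[int, dict[str, int]] = field(default_factory=dict)
    pruned_pre: int = 0
    pruned_post: int = 0

    def record(self, k: int, stage: str, count: int) -> None:
        self.candidates_per_level.setdefault(k, {})[stage] = count

    def to_dict(self) -> dict:
        return {
            "db_passes": self.db_passes,
            "candidates_per_level": {str(k): dict(v) for k, v in self.candidates_per_level.items()},
            "pruned_pre": self.pruned_pre,
            "pruned_post": self.pruned_post,
        }


def resolve_min_supp(min_supp: float, n_transactions: int) -> int:
    """Resolve a support threshold to an absolute count.

    A value in (0, 1) is a fraction of the transaction count (rounded up);
    a value >= 1 is an absolute count.  Anything else is invalid.
    """
    if 0 < min_supp < 1:
        resolved = math.ceil(min_supp * n_transactions)
    elif min_supp >= 1 and float(min_supp).is_integer():
        resolved = int(min_supp)
    else:
        raise ValueError(f"invalid min_supp {min_supp!r}: use a fraction in (0,1) or an integer >= 1")
    if resolved < 1:
        raise ValueError(f"min_supp resolves to {resolved} < 1")
    return resolved


def find_frequent_1(
    db: TransactionDB, min_supp: int, counters: MiningCounters | None = None
) -> FrequentLevel:
    """Exact single-item supports via one pass over the raw transactions."""
    if counters is not None:
        counters.db_passes += 1
    counts: Counter[int] = Counter()
    for t in db.transactions:
        counts.update(t)
    recs = tuple(
        ItemsetRecord((i,), counts[i])
        for i in range(db.n_items)
        if counts[i] >= min_supp
    )
    return FrequentLevel(k=1, itemsets=recs)


def self_join(itemsets: Sequence[Itemset], k: int) -> tuple[Itemset, ...]:
    """Prefix self-join: pairs sharing their first k-1 items yield a (k+1)-set.

    Input itemsets must be sorted tuples; output is sorted lexicographically.
    """
    items = sorted(itemsets)
    out: list[Itemset] = []
    for a_idx in range(len(items)):
        a = items[a_idx]
        for b_idx in range(a_idx + 1, len(items)):
            b = items[b_idx]
            if a[: k - 1] != b[: k - 1]:
                break  # sorted order: no later b shares the prefix
            out.append(a + (b[-1],))
    return tuple(sorted(out))


def prune_by_subsets(
    candidates: Sequence[Itemset], level_itemsets: Iterable[Itemset]
) -> tuple[Itemset, ...]:
    """Keep candidates whose every (k-1)-subset is in the given level.

    This is the sound contrapositive of downward closure: a candidate with
    any infrequent subset cannot be frequent.
    """
    level_set = set(level_itemsets)
    kept = []
    for c in candidates:
        if all(c[:i] + c[i + 1 :] in level_set for i in range(len(c))):
            kept.append(c)
    return tuple(kept)


def apriori_gen(level: FrequentLevel) -> CandidateSet:
    """Generate (k+1)-candidates: self-join then downward-closure pruning."""
    joined = self_join(level.itemset_tuples(), level.k)
    pruned = prune_by_subsets(joined, level.itemset_tuples())
    return CandidateSet(k=level.k + 1, itemsets=pruned, produced_by="after_postprune")


def _count_pass(
    db: TransactionDB, candidates: Sequence[Itemset], counters: MiningCounters
) -> dict[Itemset, int]:
    """One full raw-database pass counting each candidate's support."""
    counters.db_passes += 1
    counts = {c: 0 for c in candidates}
    cand_sets = [(c, frozenset(c)) for c in candidates]
    for t in db.transactions:
        for c, cs in cand_sets:
            if cs <= t:
                counts[c] += 1
    return counts


def mine_classic(
    db: TransactionDB, min_supp: float, max_k: int | None = None
) -> tuple[list[FrequentLevel], MiningCounters]:
    """Level-wise Apriori: one raw-database pass per level.

    Returns the nonempty frequent levels and the counters.  ``min_supp``
    may be an absolute count or a fraction of the transaction count.
    """
    threshold = resolve_min_supp(min_supp, len(db))
    counters = MiningCounters()
    levels: list[FrequentLevel] = []
    level = find_frequent_1(db, threshold, counters)
    k = 1
    while len(level) > 0 and (max_k is None or k <= max_k):
        levels.append(level)
        if max_k is not None and k == max_k:
            break
        joined = self_join(level.itemset_tuples(), level.k)
        counters.record(k + 1, "self_join", len(joined))
        cands = prune_by_subsets(joined, level.itemset_tuples())
        counters.pruned_post += len(joined) - len(cands)
        counters.record(k + 1, "after_postprune", len(cands))
        if not cands:
            break
        counts = _count_pass(db, cands, counters)
        level = FrequentLevel(
            k=k + 1,
            itemsets=tuple(
                ItemsetRecord(c, counts[c]) for c in cands if counts[c] >= threshold
            ),
        )
        k += 1
    return levels, counters
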