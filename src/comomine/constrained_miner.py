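"""The optimized miner: matrix counting + prepruning + postpruning + constraints.

The pipeline per run:

1. optionally restrict the database to transactions containing all
   pre-constraint items (e.g. a target disease such as hypertension);
2. build the length-partitioned Boolean matrices — the single pass over
   the raw transactions;
3. derive the frequent 1-item level by accumulating per-item column sums
   with early termination;
4. per level k: **preprune** the (k-1)-level (drop every itemset
   containing an item that occurs in fewer than k-1 of its itemsets — such
   an item cannot appear in any frequent k-itemset, since a frequent
   k-itemset containing it would contribute exactly k-1 frequent
   (k-1)-subsets containing it), self-join the pruned level, **postprune**
   by downward closure against the *original* (k-1)-level, then count
   candidate supports on the matrices starting at the length-k partition;
5. stop when a candidate set or frequent level comes up empty.

Supports of surviving frequent itemsets are completed to exact counts so
the rule engine can compute confidences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from comomine.classic_apriori import (
    CandidateSet,
    FrequentLevel,
    ItemsetRecord,
    MiningCounters,
    prune_by_subsets,
    resolve_min_supp,
    self_join,
)
from comomine.cluster_matrix import (
    PartitionedMatrix,
    build_partitions,
    complete_support,
    cumulative_support,
)
from comomine.transactions_io import TransactionDB

__all__ = [
    "ConstraintSpec",
    "apply_preconstraint",
    "item_frequency_index",
    "preprune",
    "constrained_self_join",
    "postprune",
    "mine",
]

Itemset = tuple[int, ...]


@dataclass(frozen=True)
class ConstraintSpec:
    """User item constraints steering the mining run.

    ``pre_items``: transactions must contain all of these to enter mining
    (the database-level filter).  ``rule_items``: an emitted rule must
    mention at least one of these.  ``constrain_join``: when True,
    candidates lacking every rule item are flagged at join time — marked
    for reporting, never dropped before rule generation.
    """

    pre_items: frozenset[int] = frozenset()
    rule_items: frozenset[int] = frozenset()
    constrain_join: bool = False

    @classmethod
    def from_labels(
        cls,
        db: TransactionDB,
        pre_labels: Iterable[str] = (),
        rule_labels: Iterable[str] = (),
        constrain_join: bool = False,
    ) -> "ConstraintSpec":
        return cls(
            pre_items=frozenset(db.id_of(lab) for lab in pre_labels),
            rule_items=frozenset(db.id_of(lab) for lab in rule_labels),
            constrain_join=constrain_join,
        )

    def validate(self, universe_size: int) -> None:
        for i in self.pre_items | self.rule_items:
            if not (0 <= i < universe_size):
                raise ValueError(f"constraint item id {i} outside universe")


def apply_preconstraint(db: TransactionDB, spec: ConstraintSpec) -> TransactionDB:
    """Retain transactions containing ALL pre-constraint items.

    An empty pre-constraint is the identity.  The universe is unchanged so
    item ids stay stable across the filter.
    """
    spec.validate(db.n_items)
    if not spec.pre_items:
        return db
    kept = tuple(t for t in db.transactions if spec.pre_items <= t)
    return TransactionDB(
        universe=db.universe,
        transactions=kept,
        source_name=f"{db.source_name}[pre-constrained]" if db.source_name else "[pre-constrained]",
    )


def item_frequency_index(level: FrequentLevel) -> dict[int, int]:
    """Map item id -> number of itemsets of the level containing it."""
    index: dict[int, int] = {}
    for rec in level.itemsets:
        for i in rec.items:
            index[i] = index.get(i, 0) + 1
    return index


def preprune(level: FrequentLevel) -> FrequentLevel:
    """Item-frequency prepruning before the self-join toward size k+1.

    Deletes every itemset containing an item that occurs in fewer than k
    itemsets of this level (k = level size = (k+1)-1).  Lossless: every
    frequent (k+1)-itemset containing item i has exactly k frequent
    k-subsets containing i, so an under-represented item can be ruled out
    before joining.
    """
    index = item_frequency_index(level)
    doomed = {i for i, c in index.items() if c < level.k}
    kept = tuple(rec for rec in level.itemsets if not doomed & set(rec.items))
    return FrequentLevel(k=level.k, itemsets=kept)


def constrained_self_join(
    level: FrequentLevel, spec: ConstraintSpec | None = None
) -> CandidateSet:
    """Prefix self-join of a (pruned) level, optionally flagging candidates.

    With ``constrain_join`` active, candidates containing none of the rule
    items are listed in ``flagged``; they remain in the candidate set so
    no frequent itemset is lost before rule generation.
    """
    joined = self_join(level.itemset_tuples(), level.k)
    flagged: tuple[Itemset, ...] = ()
    if spec is not None and spec.constrain_join and spec.rule_items:
        flagged = tuple(c for c in joined if not spec.rule_items & set(c))
    return CandidateSet(
        k=level.k + 1, itemsets=joined, produced_by="after_preprune", flagged=flagged
    )


def postprune(cands: CandidateSet, level: FrequentLevel) -> CandidateSet:
    """Downward-closure pruning against the ORIGINAL frequent level.

    The check must use the unpruned level: prepruning removes itemsets for
    join economy, not for infrequency, so testing subsets against the
    pruned level would wrongly discard viable candidates.
    """
    kept = prune_by_subsets(cands.itemsets, level.itemset_tuples())
    flagged = tuple(c for c in cands.flagged if c in set(kept))
    return CandidateSet(k=cands.k, itemsets=kept, produced_by="after_postprune", flagged=flagged)


def _frequent_1(
    pm: PartitionedMatrix, universe_size: int, threshold: int
) -> FrequentLevel:
    """Frequent single items by accumulating column sums with early stop."""
    recs = []
    for i in range(universe_size):
        if not pm.lengths:
            break
        res = cumulative_support(pm, (i,), threshold)
        if res.count >= threshold:
            res = complete_support(pm, res)
            recs.append(ItemsetRecord((i,), res.count))
    return FrequentLevel(k=1, itemsets=tuple(recs))


def mine(
    db: TransactionDB,
    min_supp: float,
    spec: ConstraintSpec | None = None,
    max_k: int | None = None,
) -> tuple[list[FrequentLevel], MiningCounters]:
    """Run the optimized miner; returns nonempty frequent levels + counters.

    Exactly one pass over the raw transactions (the matrix build) is made
    regardless of how many levels are produced.  Reported supports are
    exact (early-terminated scans are completed for surviving itemsets).
    ``min_supp`` may be an absolute count or a fraction of the (possibly
    pre-constrained) transaction count.
    """
    spec = spec if spec is not None else ConstraintSpec()
    spec.validate(db.n_items)
    db = apply_preconstraint(db, spec)
    threshold = resolve_min_supp(min_supp, len(db)) if len(db) else int(min_supp) if min_supp >= 1 else 1

    counters = MiningCounters()
    pm = build_partitions(db)
    counters.db_passes = 1  # the matrix build is the only raw-DB sweep

    levels: list[FrequentLevel] = []
    level = _frequent_1(pm, db.n_items, threshold)
    k = 1
    while len(level) > 0 and (max_k is None or k <= max_k):
        levels.append(level)
        if max_k is not None and k == max_k:
            break
        # raw join of the unpruned level, recorded for the economy report only
        raw_join = self_join(level.itemset_tuples(), level.k)
        counters.record(k + 1, "self_join", len(raw_join))

        pruned = preprune(level)
        counters.pruned_pre += len(level) - len(pruned)
        cands = constrained_self_join(pruned, spec)
        counters.record(k + 1, "after_preprune", len(cands))
        cands = postprune(cands, level)
        counters.pruned_post += counters.candidates_per_level[k + 1]["after_preprune"] - len(cands)
        counters.record(k + 1, "after_postprune", len(cands))
        if len(cands) == 0:
            break

        recs = []
        for c in cands.itemsets:
            res = cumulative_support(pm, c, threshold, start_length=cands.k)
            if res.count >= threshold:
                res = complete_support(pm, res)
                recs.append(ItemsetRecord(c, res.count))
        level = FrequentLevel(k=k + 1, itemsets=tuple(recs))
        k += 1
    return levels, counters
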