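"""Independent oracles: brute-force subset enumeration.

Deliberately naive — every itemset of every size is enumerated and its
support counted by scanning all transactions — so the oracle shares no
code path with either miner.
"""

from __future__ import annotations

from itertools import combinations

from comomine.transactions_io import TransactionDB

Itemset = tuple[int, ...]


def brute_force_support(db: TransactionDB, itemset) -> int:
    s = frozenset(itemset)
    return sum(1 for t in db.transactions if s <= t)


def brute_force_frequent(db: TransactionDB, min_supp: int) -> dict[Itemset, int]:
    """All frequent itemsets (any size) with supports, by full enumeration."""
    out: dict[Itemset, int] = {}
    items = range(db.n_items)
    max_len = max((len(t) for t in db.transactions), default=0)
    for k in range(1, max_len + 1):
        found_any = False
        for combo in combinations(items, k):
            supp = brute_force_support(db, combo)
            if supp >= min_supp:
                out[combo] = supp
                found_any = True
        if not found_any:
            break
    return out


def brute_force_rules(db: TransactionDB, min_supp: int, min_conf: float):
    """All strong rules (M, N, support count, confidence) by enumeration."""
    frequent = brute_force_frequent(db, min_supp)
    rules = []
    for itemset, supp in frequent.items():
        if len(itemset) < 2:
            continue
        for r in range(1, len(itemset)):
            for m in combinations(itemset, r):
                n = tuple(i for i in itemset if i not in m)
                conf = supp / brute_force_support(db, m)
                if conf >= min_conf:
                    rules.append((m, n, supp, conf))
    return rules


def levels_as_dict(levels) -> dict[Itemset, int]:
    """Flatten miner output levels to {itemset: support} for comparison."""
    return {rec.items: rec.support for level in levels for rec in level.itemsets}
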