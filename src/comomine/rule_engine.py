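"""Support/confidence computation and strong-rule extraction.

A rule M -> N (antecedent M, consequent N, disjoint nonempty itemsets) has

* support  S(M -> N) = supp(M ∪ N) / |D| — the fraction of transactions
  containing every item of both sides;
* confidence C(M -> N) = supp(M ∪ N) / supp(M) — the conditional
  frequency of the consequent given the antecedent.

A rule is *strong* when S >= min_supp and C >= min_conf.  Strong rules are
enumerated from the frequent itemsets: each frequent itemset of size >= 2
contributes one rule per nonempty proper subset taken as antecedent.  All
supports entering these formulas must be exact counts — early-terminated
lower bounds are rejected.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from comomine.classic_apriori import FrequentLevel, resolve_min_supp
from comomine.cluster_matrix import SupportResult
from comomine.constrained_miner import ConstraintSpec
from comomine.transactions_io import TransactionDB

__all__ = [
    "AssociationRule",
    "Thresholds",
    "SupportIndex",
    "rule_support",
    "rule_confidence",
    "strong_rules",
    "rules_to_csv",
    "rules_to_json",
]

Itemset = tuple[int, ...]


@dataclass(frozen=True)
class Thresholds:
    """Mining thresholds: min_supp (count or fraction), min_conf fraction."""

    min_supp: float
    min_conf: float

    def __post_init__(self) -> None:
        if not (0 < self.min_conf <= 1):
            raise ValueError(f"min_conf must be in (0, 1], got {self.min_conf}")

    def resolved_min_supp(self, n_transactions: int) -> int:
        return resolve_min_supp(self.min_supp, n_transactions)


@dataclass(frozen=True)
class AssociationRule:
    """A rule antecedent -> consequent with its support and confidence."""

    antecedent: Itemset
    consequent: Itemset
    support_count: int
    support_frac: float
    confidence: float

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be nonempty")
        if set(self.antecedent) & set(self.consequent):
            raise ValueError("antecedent and consequent must be disjoint")


class SupportIndex:
    """Exact itemset supports backing rule computations.

    Built from frequent levels (whose recorded supports are exact by the
    miners' contract) or directly from a database by counting.  Feeding an
    early-terminated :class:`~comomine.cluster_matrix.SupportResult` is an
    error: a lower bound would silently corrupt confidences.
    """

    def __init__(self, counts: Mapping[Itemset, int] | None, n_transactions: int):
        self._counts: dict[frozenset[int], int] = {}
        self.n_transactions = n_transactions
        if counts:
            for items, c in counts.items():
                self.add(items, c)

    def add(self, items: Iterable[int], count: int | SupportResult) -> None:
        if isinstance(count, SupportResult):
            if not count.exact:
                raise ValueError(
                    f"support of {tuple(count.itemset)} is an early-stop lower bound; "
                    "complete the scan before computing rules"
                )
            count = count.count
        self._counts[frozenset(items)] = int(count)

    def count(self, items: Iterable[int]) -> int:
        key = frozenset(items)
        try:
            return self._counts[key]
        except KeyError:
            raise KeyError(f"no exact support recorded for {tuple(sorted(key))}") from None

    def frac(self, items: Iterable[int]) -> float:
        return self.count(items) / self.n_transactions

    @classmethod
    def from_levels(cls, levels: Iterable[FrequentLevel], n_transactions: int) -> "SupportIndex":
        idx = cls(None, n_transactions)
        for level in levels:
            for rec in level.itemsets:
                idx.add(rec.items, rec.support)
        return idx

    @classmethod
    def from_db(cls, db: TransactionDB, itemsets: Iterable[Itemset]) -> "SupportIndex":
        idx = cls(None, len(db))
        for items in itemsets:
            s = frozenset(items)
            idx.add(items, sum(1 for t in db.transactions if s <= t))
        return idx


def _validate_sides(m: Sequence[int], n: Sequence[int]) -> tuple[Itemset, Itemset]:
    ms, ns = tuple(sorted(m)), tuple(sorted(n))
    if not ms or not ns:
        raise ValueError("rule sides must be nonempty")
    if set(ms) & set(ns):
        raise ValueError(f"rule sides must be disjoint, got {ms} and {ns}")
    return ms, ns


def rule_support(supports: SupportIndex, m: Sequence[int], n: Sequence[int]) -> tuple[int, float]:
    """Support of M -> N: count and fraction of transactions containing M ∪ N."""
    ms, ns = _validate_sides(m, n)
    count = supports.count(ms + ns)
    return count, count / supports.n_transactions


def rule_confidence(supports: SupportIndex, m: Sequence[int], n: Sequence[int]) -> float:
    """Confidence of M -> N: supp(M ∪ N) / supp(M); undefined for supp(M)=0."""
    ms, ns = _validate_sides(m, n)
    denom = supports.count(ms)
    if denom == 0:
        raise ZeroDivisionError(f"confidence undefined: antecedent {ms} has zero support")
    return supports.count(ms + ns) / denom


def strong_rules(
    levels: Iterable[FrequentLevel],
    thresholds: Thresholds,
    n_transactions: int,
    spec: ConstraintSpec | None = None,
) -> list[AssociationRule]:
    """Enumerate strong rules from frequent itemsets of size >= 2.

    Every nonempty proper subset M of a frequent itemset S yields the rule
    M -> S \\ M; it is kept iff support and confidence meet the thresholds
    and, when rule-constraint items are given, the rule mentions at least
    one of them.  Output order is deterministic: descending confidence,
    then descending support, then lexicographic.
    """
    levels = list(levels)
    supports = SupportIndex.from_levels(levels, n_transactions)
    min_count = thresholds.resolved_min_supp(n_transactions)
    rule_items = spec.rule_items if spec is not None else frozenset()

    rules: list[AssociationRule] = []
    for level in levels:
        if level.k < 2:
            continue
        for rec in level.itemsets:
            if rec.support < min_count:
                continue
            if rule_items and not rule_items & set(rec.items):
                continue
            s = rec.items
            for r in range(1, len(s)):
                for m in combinations(s, r):
                    n = tuple(i for i in s if i not in m)
                    conf = rec.support / supports.count(m)
                    if conf >= thresholds.min_conf:
                        rules.append(
                            AssociationRule(
                                antecedent=m,
                                consequent=n,
                                support_count=rec.support,
                                support_frac=rec.support / n_transactions,
                                confidence=conf,
                            )
                        )
    rules.sort(key=lambda r: (-r.confidence, -r.support_frac, r.antecedent, r.consequent))
    return rules


def rules_to_csv(rules: Iterable[AssociationRule], db: TransactionDB, path: str | Path) -> None:
    """Write rules as CSV: antecedent;consequent;support_count;support_frac;confidence."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["antecedent", "consequent", "support_count", "support_frac", "confidence"])
        for r in rules:
            writer.writerow(
                [
                    ";".join(db.labels_of(r.antecedent)),
                    ";".join(db.labels_of(r.consequent)),
                    r.support_count,
                    f"{r.support_frac:.6g}",
                    f"{r.confidence:.6g}",
                ]
            )


def rules_to_json(rules: Iterable[AssociationRule], db: TransactionDB) -> list[dict]:
    return [
        {
            "antecedent": list(db.labels_of(r.antecedent)),
            "consequent": list(db.labels_of(r.consequent)),
            "support_count": r.support_count,
            "support_frac": r.support_frac,
            "confidence": r.confidence,
        }
        for r in rules
    ]
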