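"""Transaction database I/O and the canonical in-memory model.

A transaction database is an ordered collection of itemsets — here, one
record per patient, each record the set of diagnosis codes observed for
that patient.  Presence/absence is all that is modelled: duplicate codes
within a record carry no information and are collapsed.

Two plain-text formats are supported:

* **basket** — one transaction per line, items separated by a delimiter
  (default: any whitespace); blank lines and ``#`` comment lines skipped;
* **long CSV** — columns ``transaction_id,item``, one row per
  (record, code) pair, grouped by id in first-appearance order.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = ["Item", "TransactionDB", "read_basket", "read_long_csv", "write_basket"]


@dataclass(frozen=True)
class Item:
    """A universe member: a dense integer id paired with its label."""

    id: int
    label: str


@dataclass(frozen=True)
class TransactionDB:
    """An ordered collection of itemsets over a finite item universe.

    Item ids are dense ``0..|universe|-1`` and assigned by sorted label
    order, so the same label set always yields the same ids regardless of
    input order.  Transactions are stored as frozensets of ids.
    """

    universe: tuple[Item, ...]
    transactions: tuple[frozenset[int], ...]
    source_name: str = ""

    def __post_init__(self) -> None:
        labels = [it.label for it in self.universe]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate labels in universe")
        for i, it in enumerate(self.universe):
            if it.id != i:
                raise ValueError("universe ids must be dense 0..n-1 in order")
        n = len(self.universe)
        for t in self.transactions:
            for i in t:
                if not (0 <= i < n):
                    raise ValueError(f"transaction references unknown item id {i}")

    # -- convenience ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.transactions)

    @property
    def n_items(self) -> int:
        return len(self.universe)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(it.label for it in self.universe)

    def id_of(self, label: str) -> int:
        try:
            return self._label_index[label]
        except KeyError:
            raise KeyError(f"unknown item label: {label!r}") from None

    @property
    def _label_index(self) -> dict[str, int]:
        # rebuilt on demand; dataclass is frozen so no cache slot
        return {it.label: it.id for it in self.universe}

    def labels_of(self, itemset: Iterable[int]) -> tuple[str, ...]:
        return tuple(self.universe[i].label for i in sorted(itemset))

    @classmethod
    def from_itemsets(
        cls, itemsets: Iterable[Iterable[str]], source_name: str = ""
    ) -> "TransactionDB":
        """Build a DB from label itemsets, assigning ids by sorted label."""
        rows = [tuple(t) for t in itemsets]
        labels = sorted({lab for t in rows for lab in t})
        index = {lab: i for i, lab in enumerate(labels)}
        universe = tuple(Item(i, lab) for i, lab in enumerate(labels))
        transactions = tuple(frozenset(index[lab] for lab in t) for t in rows)
        return cls(universe=universe, transactions=transactions, source_name=source_name)


def read_basket(path: str | Path, delimiter: str | None = None) -> TransactionDB:
    """Read a basket-format file: one transaction per nonblank line.

    ``delimiter=None`` splits on any whitespace.  Duplicate labels within
    a line are collapsed with a logged warning.  An empty file yields an
    empty database.
    """
    path = Path(path)
    raw_rows: list[tuple[str, ...]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            parts = [p for p in (p.strip() for p in parts) if p]
            if len(set(parts)) != len(parts):
                logger.warning(
                    "%s:%d: duplicate items within transaction collapsed", path, lineno
                )
                seen: list[str] = []
                for p in parts:
                    if p not in seen:
                        seen.append(p)
                parts = seen
            raw_rows.append(tuple(parts))
    return TransactionDB.from_itemsets(raw_rows, source_name=str(path))


def read_long_csv(path: str | Path) -> TransactionDB:
    """Read a long CSV with ``transaction_id,item`` columns.

    Rows are grouped by transaction id in first-appearance order, so the
    result is independent of row order up to that ordering.  Extra columns
    are ignored with a warning; missing required columns raise ValueError.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return TransactionDB.from_itemsets([], source_name=str(path))
        missing = {"transaction_id", "item"} - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing required column(s): {sorted(missing)}")
        extra = set(reader.fieldnames) - {"transaction_id", "item"}
        if extra:
            logger.warning("%s: ignoring extra column(s) %s", path, sorted(extra))
        groups: dict[str, list[str]] = {}
        order: list[str] = []
        for row in reader:
            tid, item = row["transaction_id"], row["item"]
            if tid not in groups:
                groups[tid] = []
                order.append(tid)
            if item not in groups[tid]:
                groups[tid].append(item)
    return TransactionDB.from_itemsets((groups[tid] for tid in order), source_name=str(path))


def write_basket(db: TransactionDB, path: str | Path, delimiter: str = " ") -> None:
    """Write a DB in basket format, items within a line sorted by id.

    Round-trips with :func:`read_basket` up to within-transaction order.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for t in db.transactions:
            fh.write(delimiter.join(db.universe[i].label for i in sorted(t)))
            fh.write("\n")
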