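"""Packaged demonstration data.

The demo database is the nine-record, five-item worked example used
throughout the documentation and tests: small enough to verify every
mining step by hand, yet rich enough to exercise partitioning (records of
length 2, 3 and 4), early-terminated counting, both pruning stages and
rule extraction.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from comomine.transactions_io import TransactionDB

__all__ = ["demo_db", "demo_synth_spec_path"]

_DEMO_TRANSACTIONS = (
    ("a1", "a2", "a5"),
    ("a2", "a4"),
    ("a2", "a3"),
    ("a1", "a2", "a4"),
    ("a1", "a3"),
    ("a2", "a3"),
    ("a1", "a3"),
    ("a1", "a2", "a3", "a5"),
    ("a1", "a2", "a3"),
)


def demo_db() -> TransactionDB:
    """The 9-transaction demonstration database over items a1..a5."""
    return TransactionDB.from_itemsets(_DEMO_TRANSACTIONS, source_name="demo")


def demo_synth_spec_path() -> Path:
    """Path to the packaged synthetic-data demo config (YAML)."""
    return Path(resources.files("comomine").joinpath("data/demo_synth.yaml"))
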