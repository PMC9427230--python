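"""Seeded synthetic comorbidity transaction generator.

Emulates sparse diagnosis co-occurrence data: a handful of planted
high-prevalence comorbidity patterns (e.g. {hypertension, diabetes}) over
a larger universe of background codes, each included independently at a
low marginal rate.  Patterns are all-or-none per transaction — a patient
either carries the whole pattern or none of it — which keeps the expected
supports in closed form.

Real diagnosis data has features this mechanism deliberately omits:
correlated background noise, code hierarchies, visit/temporal structure
and covariate-driven prevalence.  The generator is for property tests and
benchmarks, not epidemiological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from comomine.transactions_io import TransactionDB

__all__ = ["SyntheticSpec", "generate", "expected_supports", "load_spec"]

_MAX_REGEN = 1000  # consecutive empty-transaction retries before giving up


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic comorbidity database.

    ``planted_patterns`` is a list of (label tuple, prevalence) pairs; a
    transaction includes all items of a pattern with that probability.
    ``noise_marginals`` is either one background inclusion probability for
    every item or a per-label mapping.  ``length_cap`` truncates oversized
    transactions by dropping random background (non-planted) items.
    """

    n_transactions: int
    universe_size: int
    planted_patterns: tuple[tuple[tuple[str, ...], float], ...] = ()
    noise_marginals: float | Mapping[str, float] = 0.05
    length_cap: int | None = None
    seed: int = 0
    item_labels: tuple[str, ...] | None = None  # default: generated codes d00..dNN

    def __post_init__(self) -> None:
        if self.n_transactions < 0 or self.universe_size < 1:
            raise ValueError("need n_transactions >= 0 and universe_size >= 1")
        if self.item_labels is not None and (
            len(self.item_labels) != self.universe_size
            or len(set(self.item_labels)) != self.universe_size
        ):
            raise ValueError("item_labels must be universe_size distinct labels")
        labels = set(self.labels())
        for pat, prev in self.planted_patterns:
            if not (0 <= prev <= 1):
                raise ValueError(f"prevalence {prev} outside [0, 1]")
            if not set(pat) <= labels:
                raise ValueError(f"pattern {pat} outside the universe")
        for m in self._marginal_array():
            if not (0 <= m <= 1):
                raise ValueError("noise marginals must lie in [0, 1]")

    def labels(self) -> tuple[str, ...]:
        if self.item_labels is not None:
            return self.item_labels
        width = len(str(self.universe_size - 1))
        return tuple(f"d{i:0{width}d}" for i in range(self.universe_size))

    def _marginal_array(self) -> np.ndarray:
        if isinstance(self.noise_marginals, Mapping):
            return np.array([self.noise_marginals.get(lab, 0.0) for lab in self.labels()])
        return np.full(self.universe_size, float(self.noise_marginals))


def generate(spec: SyntheticSpec) -> TransactionDB:
    """Draw a seeded database; identical spec (incl. seed) -> identical DB.

    Per transaction: each planted pattern is included wholesale with its
    prevalence, then each background item independently with its marginal.
    Empty draws are discarded and redrawn (bounded retries); with a length
    cap, excess background items are dropped at random, planted items kept.
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels()
    index = {lab: i for i, lab in enumerate(labels)}
    patterns = [(np.array([index[lab] for lab in pat]), prev) for pat, prev in spec.planted_patterns]
    marginals = spec._marginal_array()

    rows: list[tuple[str, ...]] = []
    failures = 0
    while len(rows) < spec.n_transactions:
        present = rng.random(spec.universe_size) < marginals
        planted = np.zeros(spec.universe_size, dtype=bool)
        for ids, prev in patterns:
            if rng.random() < prev:
                planted[ids] = True
        present |= planted
        ids = np.flatnonzero(present)
        if ids.size == 0:
            failures += 1
            if failures >= _MAX_REGEN:
                raise RuntimeError(
                    f"no nonempty transaction in {_MAX_REGEN} consecutive draws; "
                    "all inclusion probabilities are (near) zero"
                )
            continue
        failures = 0
        if spec.length_cap is not None and ids.size > spec.length_cap:
            background = ids[~planted[ids]]
            keep_planted = ids[planted[ids]]
            room = max(spec.length_cap - keep_planted.size, 0)
            kept_bg = rng.choice(background, size=min(room, background.size), replace=False)
            ids = np.sort(np.concatenate([keep_planted, kept_bg]))
        rows.append(tuple(labels[i] for i in ids))
    return TransactionDB.from_itemsets(rows, source_name=f"synthetic(seed={spec.seed})")


def expected_supports(spec: SyntheticSpec) -> dict[tuple[str, ...], float]:
    """Closed-form expected support fraction per planted pattern and item.

    Requires pairwise-disjoint patterns (overlap breaks the closed form
    and is rejected) and no length cap (truncation distorts marginals).
    A pattern is present when planted OR when all its members arrive via
    independent noise; an item when its pattern is planted OR its own
    noise fires:  1 - (1 - prevalence)(1 - marginal).

    Because empty draws are discarded and redrawn, the emitted database is
    conditioned on non-emptiness; every presence probability is therefore
    divided by 1 - P(empty draw).  When the empty probability is
    negligible (large universe or appreciable marginals) this reduces to
    the plain inclusion-exclusion forms above.
    """
    if spec.length_cap is not None:
        raise ValueError("expected supports are not available with a length cap")
    seen: set[str] = set()
    for pat, _ in spec.planted_patterns:
        if seen & set(pat):
            raise ValueError("planted patterns must be pairwise disjoint")
        seen |= set(pat)
    marginals = dict(zip(spec.labels(), spec._marginal_array()))

    p_empty = math.prod(1 - prev for _, prev in spec.planted_patterns) * math.prod(
        1 - m for m in marginals.values()
    )
    if p_empty >= 1:
        raise ValueError("all inclusion probabilities are zero; generation is infeasible")
    nonempty = 1 - p_empty

    out: dict[tuple[str, ...], float] = {}
    prevalence_of: dict[str, float] = {}
    for pat, prev in spec.planted_patterns:
        noise_all = math.prod(marginals[lab] for lab in pat)
        out[tuple(pat)] = (prev + (1 - prev) * noise_all) / nonempty
        for lab in pat:
            prevalence_of[lab] = prev
    for lab in spec.labels():
        prev = prevalence_of.get(lab, 0.0)
        out[(lab,)] = (1 - (1 - prev) * (1 - marginals[lab])) / nonempty
    return out


def load_spec(path: str | Path) -> SyntheticSpec:
    """Load a SyntheticSpec from a YAML config file.

    Keys: n_transactions, universe_size, patterns (list of {items,
    prevalence}), noise (float or {label: float}), length_cap, seed.
    """
    with Path(path).open("r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    patterns = tuple(
        (tuple(p["items"]), float(p["prevalence"])) for p in cfg.get("patterns", [])
    )
    return SyntheticSpec(
        n_transactions=int(cfg["n_transactions"]),
        universe_size=int(cfg["universe_size"]),
        planted_patterns=patterns,
        noise_marginals=cfg.get("noise", 0.05),
        length_cap=cfg.get("length_cap"),
        seed=int(cfg.get("seed", 0)),
        item_labels=tuple(cfg["item_labels"]) if "item_labels" in cfg else None,
    )
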