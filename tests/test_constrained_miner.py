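import numpy as np
import pytest

from comomine.classic_apriori import FrequentLevel, ItemsetRecord, mine_classic
from comomine.constrained_miner import (
    ConstraintSpec,
    apply_preconstraint,
    constrained_self_join,
    item_frequency_index,
    mine,
    postprune,
    preprune,
)
from comomine.transactions_io import TransactionDB
from conftest import random_db
from oracles import brute_force_frequent, brute_force_support, levels_as_dict

DEMO_L2 = FrequentLevel(
    k=2,
    itemsets=(
        ItemsetRecord((0, 1), 4),  # {a1,a2}
        ItemsetRecord((0, 2), 4),  # {a1,a3}
        ItemsetRecord((0, 4), 2),  # {a1,a5}
        ItemsetRecord((1, 2), 4),  # {a2,a3}
        ItemsetRecord((1, 3), 2),  # {a2,a4}
        ItemsetRecord((1, 4), 2),  # {a2,a5}
    ),
)


def test_preconstraint_filters_to_containing_transactions(demo):
    spec = ConstraintSpec.from_labels(demo, pre_labels=["a5"])
    sub = apply_preconstraint(demo, spec)
    assert len(sub) == 2
    assert all(demo.id_of("a5") in t for t in sub.transactions)


def test_preconstraint_empty_is_identity(demo):
    assert apply_preconstraint(demo, ConstraintSpec()) is demo


def test_preconstraint_unknown_label_raises(demo):
    with pytest.raises(KeyError):
        ConstraintSpec.from_labels(demo, pre_labels=["nope"])


def test_preconstraint_unsatisfiable_gives_empty_db(demo):
    # a4 and a5 never co-occur in the demo DB
    spec = ConstraintSpec.from_labels(demo, pre_labels=["a4", "a5"])
    assert len(apply_preconstraint(demo, spec)) == 0


def test_item_frequency_index_demo_l2():
    index = item_frequency_index(DEMO_L2)
    assert index == {0: 3, 1: 4, 2: 2, 3: 1, 4: 2}


def test_preprune_removes_underrepresented_item():
    """a4 occurs in only 1 < 2 itemsets of L2, so {a2,a4} is deleted."""
    pruned = preprune(DEMO_L2)
    assert pruned.itemset_tuples() == ((0, 1), (0, 2), (0, 4), (1, 2), (1, 4))


def test_preprune_identity_when_all_items_common():
    level = FrequentLevel(
        k=2, itemsets=tuple(ItemsetRecord(t, 3) for t in [(0, 1), (0, 2), (1, 2)])
    )
    assert preprune(level).itemset_tuples() == level.itemset_tuples()


def test_preprune_never_removes_subset_of_frequent_superset():
    """Safety: prepruning never discards a subset of a frequent (k+1)-set."""
    rng = np.random.default_rng(41)
    for _ in range(30):
        db = random_db(rng)
        truth = brute_force_frequent(db, 2)
        by_k = {}
        for items, supp in truth.items():
            by_k.setdefault(len(items), {})[items] = supp
        for k in sorted(by_k):
            level = FrequentLevel(
                k=k, itemsets=tuple(ItemsetRecord(t, s) for t, s in sorted(by_k[k].items()))
            )
            removed = set(level.itemset_tuples()) - set(preprune(level).itemset_tuples())
            for sup_set in by_k.get(k + 1, {}):
                for dropped in removed:
                    assert not set(dropped) <= set(sup_set)


def test_constrained_self_join_pruned_level_four_candidates():
    cands = constrained_self_join(preprune(DEMO_L2))
    assert cands.itemsets == ((0, 1, 2), (0, 1, 4), (0, 2, 4), (1, 2, 4))


def test_self_join_unpruned_level_six_candidates():
    cands = constrained_self_join(DEMO_L2)
    assert len(cands) == 6


def test_constrained_self_join_empty_level():
    level = FrequentLevel(k=2, itemsets=())
    assert len(constrained_self_join(level)) == 0


def test_join_constraint_flags_but_keeps_candidates():
    spec = ConstraintSpec(rule_items=frozenset({4}), constrain_join=True)
    cands = constrained_self_join(preprune(DEMO_L2), spec)
    assert len(cands) == 4  # nothing dropped
    assert set(cands.flagged) == {(0, 1, 2)}  # the one candidate without a5


def test_postprune_checks_against_original_level():
    """{a3,a5} is infrequent, so both candidates containing it fall."""
    cands = constrained_self_join(preprune(DEMO_L2))
    kept = postprune(cands, DEMO_L2)
    assert kept.itemsets == ((0, 1, 2), (0, 1, 4))


def test_postprune_identity_when_subsets_frequent():
    level = FrequentLevel(
        k=2, itemsets=tuple(ItemsetRecord(t, 3) for t in [(0, 1), (0, 2), (1, 2)])
    )
    cands = constrained_self_join(level)
    assert postprune(cands, level).itemsets == cands.itemsets


def test_mine_demo_final_family_and_single_pass(demo):
    levels, counters = mine(demo, 2)
    assert levels_as_dict([levels[-1]]) == {(0, 1, 2): 2, (0, 1, 4): 2}
    assert counters.db_passes == 1
    assert counters.candidates_per_level[3]["self_join"] == 6
    assert counters.candidates_per_level[3]["after_preprune"] == 4
    assert counters.candidates_per_level[3]["after_postprune"] == 2


def test_mine_threshold_above_n(demo):
    levels, _ = mine(demo, 10)
    assert levels == []


def test_mine_reports_exact_supports(demo):
    levels, _ = mine(demo, 2)
    for level in levels:
        for rec in level.itemsets:
            assert rec.support == brute_force_support(demo, rec.items)


def test_mine_equivalent_to_classic_and_oracle():
    """Cross-implementation equivalence on random databases."""
    rng = np.random.default_rng(59)
    for _ in range(50):
        db = random_db(rng)
        for min_supp in (1, 2, 3):
            matrix_levels, mc = mine(db, min_supp)
            classic_levels, cc = mine_classic(db, min_supp)
            truth = brute_force_frequent(db, min_supp)
            assert levels_as_dict(matrix_levels) == truth
            assert levels_as_dict(classic_levels) == truth
            assert mc.db_passes == 1
            assert cc.db_passes >= len(classic_levels)


def test_candidate_economy_preprune_never_worse():
    rng = np.random.default_rng(61)
    for _ in range(20):
        db = random_db(rng)
        _, counters = mine(db, 2)
        for stages in counters.candidates_per_level.values():
            assert stages["after_preprune"] <= stages["self_join"]


def test_constraint_soundness_supports_match_filtered_db(demo):
    """With a pre-constraint, supports equal brute force on the subset."""
    spec = ConstraintSpec.from_labels(demo, pre_labels=["a5"])
    sub = apply_preconstraint(demo, spec)
    levels, _ = mine(demo, 2, spec=spec)
    for level in levels:
        for rec in level.itemsets:
            assert rec.support == brute_force_support(sub, rec.items)


def test_mine_invalid_min_supp(demo):
    with pytest.raises(ValueError):
        mine(demo, 0)
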