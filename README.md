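# comomine

Constrained association-rule mining for comorbidity patterns in
chronic-disease transaction data.

Each record of the input is one patient's set of diagnosis codes. The
package mines frequent itemsets L_k (code sets with support ≥ min_supp)
and strong rules M → N with

    S(M → N) = supp(M ∪ N) / |D| ≥ min_supp,
    C(M → N) = supp(M ∪ N) / supp(M) ≥ min_conf,

and implements two interchangeable miners:

* **classic** — the instrumented level-wise Apriori baseline: prefix
  self-join of L_{k−1}, downward-closure pruning, one full database pass
  per level;
* **matrix** — an optimized miner that sweeps the raw database once,
  clustering transactions by cardinality into Boolean matrices (one row
  per record, one column per code). Itemset support is the sum of the
  column-AND, accumulated across partitions in ascending length with
  early termination at the threshold. Before the self-join, any item
  occurring in fewer than k−1 itemsets of L_{k−1} is pruned out (it
  cannot occur in a frequent k-itemset); after it, candidates with an
  infrequent subset are discarded. Item constraints restrict mining to a
  target cohort (records containing given codes) and to rules mentioning
  given codes.

Both miners provably return identical frequent families; the matrix
miner does so with one raw pass instead of one per level and with fewer
candidates. For audiences: epidemiologists and medical-informatics
analysts screening co-occurring diagnoses, and anyone wanting a small,
fully-tested constrained Apriori with honest instrumentation.

## Worked example

The packaged demo database has nine records over codes a1..a5
(`comomine.datasets.demo_db()`; write it with `write_basket`). Mining at
absolute min_supp 2 and min_conf 1.0:

```sh
comomine compare --input demo.basket --min-supp 2 --out cmp
# families identical (13 itemsets); db passes: classic 3 vs matrix 1

comomine mine --input demo.basket --min-supp 2 --min-conf 1.0 --out mined
# 13 frequent itemsets, 6 strong rules -> mined/
```

`cmp/compare.json` shows the candidate economy at level 3: the raw
self-join of the six frequent 2-itemsets yields 6 candidates
(`"self_join": 6`), prepruning the level first (a4 occurs in only one
2-itemset, so {a2,a4} leaves the join input) yields 4
(`"after_preprune": 4`), and the downward-closure check leaves 2
(`"after_postprune": 2`): {a1,a2,a3} and {a1,a2,a5}, each with support 2.
The classic miner reaches the same L3 with 3 raw passes; the matrix
miner's only pass is the matrix build.

`mined/rules.csv` holds the six confidence-1.0 rules, e.g.

```
antecedent,consequent,support_count,support_frac,confidence
a1;a5,a2,2,0.222222,1
a5,a1;a2,2,0.222222,1
...
```

— every patient with codes a1 and a5 also carries a2 (2/9 of the cohort).

Synthetic comorbidity data with planted patterns:

```sh
comomine simulate --spec src/comomine/data/demo_synth.yaml --out synth.basket
# wrote 500 transactions over 20 items to synth.basket
comomine mine --input synth.basket --min-supp 0.2 --out synth_mined
```

recovers the planted {hypertension, diabetes} pattern as a frequent
2-itemset.

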