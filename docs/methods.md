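# Methods

## Problem and model

comomine mines association rules from chronic-disease transaction data:
each record is the set of diagnosis codes observed for one patient, and
the quantities of interest are frequent comorbidity itemsets and strong
rules M → N between disjoint, nonempty code sets M and N, with

* support S(M → N) = supp(M ∪ N) / |D| — the fraction of records
  containing every code of both sides, and
* confidence C(M → N) = supp(M ∪ N) / supp(M) — the conditional
  frequency of the consequent given the antecedent.

A rule is *strong* when S ≥ min_supp and C ≥ min_conf (both comparisons
are ≥). Frequent itemsets obey downward closure — every subset of a
frequent itemset is frequent — whose contrapositive licenses all pruning
performed here. Two points where common textbook statements get garbled
deserve explicit note, because this package deliberately implements the
standard forms: the converse of downward closure ("all subsets frequent ⇒
set frequent") is false in general and is **not** used as a pruning rule;
and confidence is normalised by the antecedent's support supp(M), not the
consequent's, since the consequent-normalised ratio is not a conditional
frequency. Rule sides are required to be disjoint; without disjointness
confidence degenerates (any overlap item inflates both sides).

## The two miners

**Classic baseline** (`classic_apriori`). Level-wise Apriori: level k+1
candidates come from the prefix self-join of the frequent k-level
(itemsets sorted by item id; pairs sharing their first k−1 items join),
followed by downward-closure pruning, followed by one full pass over the
raw transactions to count supports. The pass count and per-stage
candidate counts are recorded in `MiningCounters`; they are the currency
in which the optimized miner's savings are expressed.

**Matrix miner** (`cluster_matrix` + `constrained_miner`). The raw
database is swept exactly once, clustering transactions by cardinality
into Boolean matrices: partition k holds every k-item record as a 0/1 row
over the full universe (rows keep database order; every row of partition
k sums to k). Support within a partition is the column-AND of the
itemset's member columns, summed. Because a k-itemset cannot occur in a
record shorter than k, counting a size-k candidate starts at the length-k
partition and walks partitions in ascending length, accumulating counts,
and **terminates early** the moment the running count reaches the
absolute min_supp: the frequency decision is then settled although the
count is only a lower bound. `SupportResult.exact` records whether the
scan was completed; supports of itemsets that survive into the reported
levels are always completed to exact counts, because confidences divide
by them. The stop condition is ≥ (stopping at exactly min_supp is an
early stop), which is the only reading consistent with partial
accumulation being sufficient evidence.

Candidate generation adds a second pruning stage *before* the join.
For each item i, let |L_k(i)| be the number of itemsets of the frequent
k-level containing i. A frequent (k+1)-itemset containing i has exactly k
frequent k-subsets containing i, so if |L_k(i)| < k, item i can appear in
no frequent (k+1)-itemset and every k-itemset containing i can be removed
from the join input. This **prepruning** is lossless (the removed
itemsets are frequent — they are dropped for join economy only, and they
remain in the reported level). Consequently the subsequent
**postpruning** (downward-closure check of each joined candidate's
k-subsets) must test membership against the *original* unpruned level;
testing against the pruned level would wrongly discard candidates whose
subsets were removed for economy.

Termination: the level loop stops when the post-pruned candidate set or
the resulting frequent level is empty, or at `max_k`.

## Constraints

`ConstraintSpec` carries the two user constraints: `pre_items` filters
the database before matrix construction (only records containing *all*
pre-constraint codes — e.g. a target disease — enter mining; supports are
then supports within that cohort, and a fractional min_supp resolves
against the cohort size); `rule_items` filters the emitted rules (a rule
is kept only if it mentions at least one constraint code). An optional
`constrain_join` flag additionally *flags* join candidates that contain
no rule item; flagged candidates are reported but never dropped, since
dropping them before rule generation would lose frequent itemsets whose
subsets feed other rules. The flag defaults to off because there is no
single canonical predicate for constraint-aware joining; flag-don't-drop
is the conservative choice.

## Thresholds and numerical choices

* `min_supp` in (0,1) is a fraction of the transaction count, resolved as
  ceil(frac × N); ≥ 1 is an absolute count. Non-integer values ≥ 1 are
  rejected rather than rounded. A threshold resolving below 1 is a
  configuration error.
* All itemsets are stored as tuples sorted by item id; item ids are
  assigned by sorted label, which fixes the self-join tie-break and makes
  every output deterministic for a given input. Rules are ordered by
  descending confidence, then descending support, then lexicographically.
* Duplicate codes within a record are collapsed (presence/absence
  semantics, matching the Boolean encoding) with a logged warning.
* Degenerate inputs: an empty file is an empty database, not an error;
  mining it yields no levels and one (trivial) raw pass.

## Synthetic comorbidity data

`synthdata.generate` draws seeded databases with planted patterns: per
transaction, each planted pattern (a code set with a prevalence) is
included all-or-none with its prevalence, then every code independently
with its background marginal; empty draws are discarded and redrawn
(bounded retries). All-or-none planting keeps expectations in closed
form; overlapping patterns are rejected rather than approximated.

Discarding empty draws conditions the output on non-emptiness, so every
presence probability is inflated by 1/(1 − P(empty)), where P(empty) is
the product of (1 − prevalence) over patterns times (1 − marginal) over
codes. `expected_supports` includes this factor exactly; it reduces to
the plain inclusion–exclusion values (pattern: prev + (1−prev)·∏m; item:
1 − (1−prev)(1−m)) whenever the empty probability is negligible. With a
`length_cap` the closed form does not hold and is refused.

The generator emulates sparse co-occurrence structure only. Real
diagnosis data has correlated background noise, code hierarchies,
visit/temporal structure and covariate-driven prevalence, none of which
are modelled — so passing recovery tests demonstrates correctness of the
miners on the stated mechanism, not epidemiological validity.

Default study conditions used by the recovery tests: n = 2000 records,
20-code universe, planted pattern prevalence 0.3, background marginal
0.05, mining at min_supp fraction 0.2, across 20 seeds. The oracle
cross-check suites use 200 random databases of at most 12 items and 40
transactions with min_supp ∈ {1, 2, 3} — small enough that the
brute-force subset-enumeration oracle is exact and fast, large enough to
exercise every join/prune path.

## Known limitations

* Matrices hold the full universe as columns in every partition; memory
  is O(|D|·|universe|) bits. Fine for cohort-scale data, not for
  market-basket scale universes.
* No hash-tree/trie candidate indexing, no incremental updates, no
  parallel partition scans.
* `expected_supports` covers planted patterns and single items only, not
  arbitrary itemsets.
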