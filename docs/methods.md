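# Methods

## Model and procedure

The pipeline treats a clinical table as a transaction database
T = {X₁, …, X_N}: each record becomes a set of categorical items, one per
retained attribute, rendered `attribute=level`. Two metrics drive
everything:

* **support** of a rule A ⇒ C: the fraction of transactions containing
  A ∪ {C};
* **confidence**: the fraction of transactions containing A that also
  contain C.

Mining is *class-stratified*: the cohort is split by disease status and
frequent itemsets are mined inside each group, with the group's class
item as fixed rule consequent and group size as the support denominator.
Two consequences follow directly and are asserted as tests:

1. every rule's confidence is exactly 1.0 (the class item is in every
   transaction of its group), so the confidence threshold (default 0.9)
   never filters within this design — it matters only if the pipeline is
   pointed at non-stratified data;
2. a rule's support equals the support of its antecedent within the
   group, so supports like 0.88 in a group that is 6 % of the cohort are
   group-relative by construction, never cohort-relative.

Rules are *frequent* iff support ≥ min_support and confidence ≥
min_confidence, both inclusive; everything else — including
low-support/high-confidence rules — is infrequent and not reported.

## The two miners and the consensus stage

Apriori and FP-Growth are implemented independently and share no counting
code.

* **Apriori**: count single items; join frequent k-itemsets sharing a
  sorted (k−1)-prefix into (k+1)-candidates; prune candidates with an
  infrequent k-subset; count survivors by subset scan. Canonical item
  order is lexicographic on the rendered string, making candidate
  generation deterministic.
* **FP-Growth**: transactions are rewritten with frequent items in
  descending support order (ties broken lexicographically — the
  published procedure specifies only "descending", and a total order is
  required for determinism) and inserted into a prefix tree with
  per-node counts and per-item header chains. Mining recurses over
  suffix items in ascending header order, rebuilding each conditional
  pattern base as a smaller tree.

Both compute exact integer counts, so their outputs must be identical;
the consensus stage intersects the two rule sets and reports exclusive
rules and metric discrepancies. Its default tolerance is 0: agreement is
not a statistical question here but an integrity check, and any
disagreement is a bug detector. A tolerance knob exists for comparing
against approximate or external rule sets.

## Numerical choices

* Thresholds written as decimals are honored as decimals:
  `Fraction(repr(0.6)) = 3/5`, and an itemset is frequent iff
  `count ≥ ceil(min_support · N)` in exact rational arithmetic. This
  keeps itemsets sitting exactly at the threshold (support 0.60 on the
  nose) in the output and avoids float-comparison artifacts entirely.
  All supports and confidences are `Fraction`s internally.
* Reported metrics round half-up to two decimals; exact values are
  preserved in the JSON serialization (numerator/denominator pairs).
* Laboratory reference intervals are closed on both ends
  (lo ≤ x ≤ hi ⇒ Normal); age decade bins are half-open [lo, hi) except
  the last, which is closed, so boundary ages map to exactly one bin.
  Values outside every bin raise by default; a `drop` mode removes such
  records and surfaces the count in the stage log.
* Boolean spellings ({f,t}, {0,1}, {N,Y}, yes/no) normalize to
  {False, True} so rules from different source dialects render uniformly.
* Rule sets are kept in canonical order (descending support, ascending
  rendered antecedent); artifacts are written atomically (temp dir +
  rename) so a crashed run leaves no partial outputs.

## Tunable parameters

| parameter | default | why |
|---|---|---|
| min_support | 0.6 | the study design's screening threshold; group-relative fraction in (0,1] |
| min_confidence | 0.9 | inert under stratification (see above) but enforced for non-stratified inputs |
| max_antecedent (pipeline) | 3 | cohorts put most records at the reference level of most attributes, so many near-universal items coexist; unlimited mining is combinatorially explosive (≈3.6·10⁵ frequent itemsets at support 0.6 on a 600-record cohort with ~18 such items) while reported rule depth is 3. Library miners default to unlimited; set `max_antecedent: null` in the run config to lift the cap |
| metric_tolerance (consensus) | 0 | exact miners must agree exactly |
| missing_rate (dataset1-like preset) | 0.0066/cell | over 21 columns ≈ 13 % of records incomplete, the attrition a complete-case clean of this cohort shape shows |

## Synthetic cohorts and what they do (not) show

The generator emulates the *statistical shape* of small clinical
cohorts: a class column with strong imbalance, boolean history/
comorbidity attributes concentrated at their reference level, lab values
drawn inside or outside reference ranges, decade or threshold age
structure, uniform cell-level missingness, and *planted patterns* —
itemsets forced to co-occur within a class at a known probability.

Planting is a per-record mixture: with probability p the whole pattern
is written; otherwise attributes are drawn from residual marginals
rescaled so the configured per-class marginals still hold (feasible only
when p ≤ each item's marginal; infeasible configurations are rejected,
as are patterns sharing an attribute within one class). The realized
joint probability is p plus accidental co-occurrence under the residual
draws; it equals p exactly when some pattern item's marginal equals p,
which the recovery preset exploits by pinning marginals to the planted
probabilities (0.95/0.75/0.55). Ground truth is recorded by direct
recount of the generated level matrix before missingness, so tests
against it are exact.

Draw order is fixed (class → pattern masks → attributes in configuration
order → missingness) from a single seeded generator, so equal
configurations produce byte-identical tables.

What passing synthetic tests shows: the encode/stratify/mine/consensus
machinery is count-exact, recovers planted effect sizes within binomial
sampling error, and rejects sub-threshold patterns. What it does not
show: anything about real cohorts' dependence structure — attributes are
conditionally independent within class apart from the planted patterns,
missingness is completely at random, and no measurement error or label
noise is modeled. Reproduction of published numbers therefore runs
against the real downloads, never against the generator.

## Problem sizes

The randomized miner-equivalence checks use databases of up to 200
transactions over at most 12 distinct items, the regime where the
exhaustive power-set oracle (numpy bitmask counting over all 2^m − 1
itemsets) is itself trustworthy and fast; 200 such databases with random
thresholds run in a few seconds. Pattern-recovery uses 5,000 records per
class, giving a binomial SE of ≈0.006–0.007 at the planted
probabilities, an order of magnitude smaller than the 0.05 gap between
the 0.55 pattern and the 0.6 threshold. Synthetic end-to-end runs use
600–2,800 records, matching the real cohorts' scale.

## Known limitations

* Only class-consequent rules are generated; general item → item rules,
  lift/leverage/conviction metrics, and significance testing are out of
  scope by design.
* Complete-case cleaning only; no imputation.
* The thyroid cohort's published preprocessing is ambiguous in one
  respect: its age bins span 20–80, which may imply an age-range filter
  on top of missing-value removal. Both cleanings are implemented
  (`clean_dataset1(..., age_filter=...)`); the default is plain
  complete-case removal, and the alternative count is one call away.
* The miners are clarity-first pure Python (no hash trees, FP-arrays or
  partitioning); they are meant for tens of attributes and thousands of
  records, with the antecedent cap as the lever for dense cohorts.
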