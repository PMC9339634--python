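# thyromine

Class-stratified association rule mining for clinical risk-factor
discovery, built around two independent frequent-itemset miners — a
level-wise Apriori and an FP-tree (FP-Growth) implementation — whose
exact agreement is used as the pipeline's integrity check.

## The problem

Given a cohort of patient records (demographics, medical history,
comorbidities, laboratory results) and a binary disease status, which
attribute combinations co-occur strongly with the disease? The pipeline
encodes each record as a *transaction* of categorical items
(`T3=Abnormal`, `Hypertension=True`, …), splits the cohort into
disease-positive and disease-negative groups, and mines, within each
group, association rules

```
A ⇒ C        support(A ⇒ C) = freq(A ∪ {C}) / N
             confidence(A ⇒ C) = freq(A ∪ {C}) / freq(A)
```

whose consequent `C` is the group's class item and whose antecedent `A`
is a frequent itemset, keeping rules with support ≥ 0.6 and confidence
≥ 0.9 (both thresholds configurable, comparisons inclusive and computed
on exact integer counts). Because mining is stratified — the class item
is present in every transaction of its group — every emitted rule has
confidence exactly 1.0; the support column carries the information.

Both miners always run; their rule sets are intersected and only *mutual*
rules are reported. Since both compute exact counts, any non-mutual rule
indicates an implementation fault, never a finding.

Target users are biostatisticians and epidemiologists doing exploratory
risk-factor screens on small categorical cohorts (hundreds to a few
thousand records, tens of attributes), not large-scale market-basket
workloads.

## Worked example

Generate a cardiology-registry-shaped synthetic cohort with planted
patterns and mine it:

```
$ thyromine simulate --preset dataset2 --seed 7 --n 400 --out out/
read: 400 records, 15 attributes
select: 15 attributes retained
clean: 400 -> 400 records (removed 0 incomplete)
discretize: 400 transactions, 29 distinct items
group Negative: 383 transactions
group Positive: 17 transactions
mine[apriori] group Negative: 154 rules
mine[fpgrowth] group Negative: 154 rules
consensus group Negative: 154 mutual, 0/0 exclusive
mine[apriori] group Positive: 225 rules
mine[fpgrowth] group Positive: 225 rules
consensus group Positive: 225 mutual, 0/0 exclusive
```

The stage log shows the record counts after every stage and that the two
miners agreed exactly (`0/0 exclusive`). The preset plants
`Hypertension=True` in the disease-positive group at probability 0.71;
the mined rule set (`out/rules_Positive_apriori.csv`) recovers it:

```
group,antecedents,consequent,support,confidence,count
Positive,Hypertension=True,Class=Positive,0.71,1.00,12
```

i.e. 12 of the 17 disease-positive records carry hypertension (support
12/17 ≈ 0.71), and — as for every stratified rule — confidence is 1.00.
`out/ground_truth.json` holds the generator's realized per-group counts
for every item and planted pattern, so mined supports can be checked
against truth.

Real data goes through the same path:

```
thyromine mine --input data/sick.data --dialect uci_data --preset dataset1
thyromine compare out/rules_Positive_apriori.json out/rules_Positive_fpgrowth.json
```

or through a YAML config (`thyromine mine --config run.yaml`) carrying
the attribute selection, discretization rules, thresholds and output
directory.

## Library layout

| module | contents |
|---|---|
| `thyromine.ingest` | UCI `.data` / CSV / xlsx readers, attribute selection, complete-case cleaning |
| `thyromine.discretize` | interval/boolean/categorical discretization rules, bundled schemes for the two study cohorts, transaction encoding, class stratification |
| `thyromine.apriori` | level-wise miner with join+prune candidate generation |
| `thyromine.fpgrowth` | FP-tree construction, conditional pattern bases, recursive mining |
| `thyromine.rules` | support/confidence, class-targeted rule generation, frequent/infrequent categorization, CSV/JSON reports |
| `thyromine.consensus` | mutual-rule intersection and discrepancy reporting |
| `thyromine.synthetic_data` | seeded cohort generator with planted patterns and ground truth |
| `thyromine.pipeline` / `thyromine.cli` | end-to-end orchestration and the `thyromine` command |

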