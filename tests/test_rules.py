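from fractions import Fraction

import pytest

from conftest import random_db
from thyromine.apriori import apriori_mine
from thyromine.discretize import TransactionDB
from thyromine.rules import (
    AssociationRule, RuleError, RuleSet, Thresholds, categorize_rule,
    confidence_of, generate_class_rules, round2, support_of,
)


def db_of(*itemsets):
    return TransactionDB.from_itemsets(itemsets)


A, B, C = "a=1", "b=1", "c=1"
CLS = "Class=Positive"


class TestSupportOf:
    def test_everywhere(self):
        db = db_of({A, B}, {A, B, C})
        assert support_of(db, frozenset({A, B})) == (2, Fraction(1))

    def test_absent(self):
        db = db_of({A}, {B})
        assert support_of(db, frozenset({C})) == (0, Fraction(0))

    def test_direct_count(self):
        db = db_of({A, B}, {A}, {B})
        assert support_of(db, frozenset({A, B})) == (1, Fraction(1, 3))

    def test_empty_itemset_rejected(self):
        with pytest.raises(RuleError):
            support_of(db_of({A}), frozenset())


class TestConfidenceOf:
    def test_consequent_always_present(self):
        db = db_of({A, C}, {A, C}, {B})
        assert confidence_of(db, frozenset({A}), C) == 1

    def test_direct_count(self):
        db = db_of({A, C}, {A}, {C})
        assert confidence_of(db, frozenset({A}), C) == Fraction(1, 2)

    def test_equals_support_ratio(self, rng):
        for _ in range(10):
            db = random_db(rng, max_n=40, max_items=6)
            universe = sorted(db.item_universe)
            if len(universe) < 2:
                continue
            a, c = universe[0], universe[1]
            ca, _ = support_of(db, frozenset({a}))
            if ca == 0:
                continue
            _, s_ac = support_of(db, frozenset({a, c}))
            _, s_a = support_of(db, frozenset({a}))
            assert confidence_of(db, frozenset({a}), c) == s_ac / s_a

    def test_undefined_when_antecedent_absent(self):
        with pytest.raises(RuleError, match="undefined"):
            confidence_of(db_of({A}), frozenset({B}), A)


class TestThresholds:
    def test_study_defaults(self):
        th = Thresholds()
        assert th.support_fraction == Fraction(3, 5)
        assert th.confidence_fraction == Fraction(9, 10)

    @pytest.mark.parametrize("kw", [
        {"min_support": 0}, {"min_confidence": 1.2}, {"min_support": -0.1},
    ])
    def test_out_of_range_rejected(self, kw):
        with pytest.raises(RuleError):
            Thresholds(**kw)


class TestGenerateClassRules:
    def mine_rules(self, itemsets, th=None, **kw):
        th = th or Thresholds()
        db = db_of(*itemsets)
        frequent = apriori_mine(db, th.min_support)
        return generate_class_rules(db, CLS, frequent, th, **kw)

    def test_uniform_group(self):
        rs = self.mine_rules([{A, CLS}] * 4)
        rule = rs.by_key()[((A,), CLS)]
        assert rule.support == 1 and rule.confidence == 1 and rule.count == 4

    def test_stratified_confidence_is_always_one(self, rng):
        total = 0
        for _ in range(10):
            base = random_db(rng, max_n=60, max_items=7)
            db = db_of(*[t | {CLS} for t in base.itemsets()])
            th = Thresholds(min_support=round(float(rng.uniform(0.1, 0.7)), 2))
            frequent = apriori_mine(db, th.min_support)
            rs = generate_class_rules(db, CLS, frequent, th)
            assert all(r.confidence == 1 for r in rs.rules)
            total += len(rs.rules)
        assert total > 0  # the property was exercised on real rules

    def test_class_item_never_in_antecedent(self):
        rs = self.mine_rules([{A, B, CLS}] * 3)
        assert all(CLS not in r.antecedent for r in rs.rules)
        assert {tuple(sorted(r.antecedent)) for r in rs.rules} == {
            (A,), (B,), (A, B)}

    def test_threshold_filtering(self):
        # a appears in 2/5 -> support 0.4 < 0.6, must be filtered
        rs = self.mine_rules(
            [{A, CLS}, {A, CLS}, {B, CLS}, {B, CLS}, {B, CLS}],
            th=Thresholds(min_support=0.4, min_confidence=0.9))
        keys = {k[0] for k in rs.by_key()}
        assert (B,) in keys and (A,) in keys
        rs2 = self.mine_rules(
            [{A, CLS}, {A, CLS}, {B, CLS}, {B, CLS}, {B, CLS}],
            th=Thresholds(min_support=0.6, min_confidence=0.9))
        assert {k[0] for k in rs2.by_key()} == {(B,)}

    def test_max_antecedent(self):
        rs = self.mine_rules([{A, B, CLS}] * 3, max_antecedent=1)
        assert all(len(r.antecedent) == 1 for r in rs.rules)

    def test_stratification_violation(self):
        db = db_of({A, CLS}, {A})
        frequent = apriori_mine(db, 0.5)
        with pytest.raises(RuleError, match="stratif"):
            generate_class_rules(db, CLS, frequent, Thresholds())

    def test_support_monotone_in_antecedent(self, rng):
        base = random_db(rng, max_n=60, max_items=6)
        db = db_of(*[t | {CLS} for t in base.itemsets()])
        frequent = apriori_mine(db, 0.2)
        rs = generate_class_rules(db, CLS, frequent,
                                  Thresholds(min_support=0.2))
        by_key = rs.by_key()
        for rule in rs.rules:
            for item in rule.antecedent:
                if len(rule.antecedent) > 1:
                    sub = tuple(sorted(rule.antecedent - {item}))
                    assert by_key[(sub, CLS)].support >= rule.support


class TestCategorize:
    @pytest.mark.parametrize("support,confidence,expected", [
        (0.88, 1.00, "frequent"),
        (0.3, 0.95, "infrequent"),   # low support, high confidence
        (0.6, 0.9, "frequent"),      # inclusive boundary
        (0.7, 0.85, "infrequent"),
    ])
    def test_categorization(self, support, confidence, expected):
        rule = AssociationRule(
            antecedent=frozenset({A}), consequent=CLS,
            count=1, support=Fraction(str(support)),
            confidence=Fraction(str(confidence)))
        assert categorize_rule(rule, Thresholds(0.6, 0.9)) == expected


class TestRuleSetReporting:
    def rule(self, ant, sup_num, sup_den):
        return AssociationRule(
            antecedent=frozenset(ant), consequent=CLS,
            count=sup_num, support=Fraction(sup_num, sup_den),
            confidence=Fraction(1))

    def test_half_up_rounding(self):
        assert round2(Fraction(885, 1000)) == 0.89
        assert round2(Fraction(61, 100)) == 0.61
        assert round2(0.875) == 0.88

    def test_canonical_order(self):
        rs = RuleSet(rules=[self.rule([B], 1, 2), self.rule([A], 3, 4),
                            self.rule([A, B], 1, 2)])
        assert [r.render_antecedent() for r in rs.rules] == \
            [A, f"{A}; {B}", B]

    def test_duplicates_rejected(self):
        with pytest.raises(RuleError):
            RuleSet(rules=[self.rule([A], 1, 2), self.rule([A], 1, 2)])

    def test_csv_layout(self):
        rs = RuleSet(rules=[self.rule([A, B], 7, 8)],
                     provenance={"group": "Positive"})
        lines = rs.to_csv().splitlines()
        assert lines[0] == "group,antecedents,consequent,support,confidence,count"
        assert lines[1] == f"Positive,{A}; {B},{CLS},0.88,1.00,7"

    def test_json_roundtrip_preserves_exact_metrics(self):
        rs = RuleSet(rules=[self.rule([A], 2, 3)],
                     provenance={"algorithm": "apriori"})
        back = RuleSet.from_json(rs.to_json())
        assert back.rules[0].support == Fraction(2, 3)
        assert back.provenance["algorithm"] == "apriori"

    def test_rule_invariants(self):
        with pytest.raises(RuleError):
            AssociationRule(frozenset(), CLS, 1, Fraction(1), Fraction(1))
        with pytest.raises(RuleError):
            AssociationRule(frozenset({CLS}), CLS, 1, Fraction(1), Fraction(1))
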