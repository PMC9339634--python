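"""Association-rule metrics and class-targeted rule generation.

For a rule A ⇒ C over a database of N transactions:

* support  = count(A ∪ {C}) / N   (occurrence frequency of the whole rule)
* confidence = count(A ∪ {C}) / count(A)   (conditional frequency of C
  given A)

Rules are generated within a class-stratified group with the group's class
item as the fixed consequent, so N is the group size and — because the
class item appears in every transaction of its group — every emitted
rule's confidence is exactly 1. Rules are kept only if both support and
confidence meet their thresholds (inclusive); everything else, including
low-support/high-confidence rules, is categorized infrequent.

Metrics are exact rationals internally; reported values round half-up to
two decimals.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Mapping

from .apriori import FrequentItemsets, ItemsetSupport, as_fraction
from .discretize import Item, TransactionDB


class RuleError(Exception):
    """Raised for undefined metrics or stratification violations."""


def support_of(db: TransactionDB, items: frozenset[str]) -> tuple[int, Fraction]:
    """Exact (count, fraction) of transactions containing ``items``."""
    if not items:
        raise RuleError("support of the empty itemset is not defined here")
    if db.N < 1:
        raise RuleError("empty database")
    count = sum(1 for t in db.itemsets() if items <= t)
    return count, Fraction(count, db.N)


def confidence_of(db: TransactionDB, antecedent: frozenset[str], consequent: str) -> Fraction:
    """count(A ∪ {C}) / count(A); undefined when A never occurs."""
    count_a, _ = support_of(db, antecedent)
    if count_a == 0:
        raise RuleError(f"confidence undefined: antecedent {sorted(antecedent)} absent")
    count_ac = sum(
        1 for t in db.itemsets() if antecedent <= t and consequent in t
    )
    return Fraction(count_ac, count_a)


def round2(x: Fraction | float) -> float:
    """Half-up rounding to 2 decimals, as printed in reports."""
    d = Decimal(x.numerator) / Decimal(x.denominator) if isinstance(x, Fraction) \
        else Decimal(repr(x))
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Thresholds:
    """Minimum support and confidence for a rule to count as frequent."""

    min_support: float | str | Fraction = 0.6
    min_confidence: float | str | Fraction = 0.9

    def __post_init__(self) -> None:
        for name, v in (("min_support", self.min_support),
                        ("min_confidence", self.min_confidence)):
            f = as_fraction(v)
            if not 0 < f <= 1:
                raise RuleError(f"{name} must be in (0, 1], got {v}")

    @property
    def support_fraction(self) -> Fraction:
        return as_fraction(self.min_support)

    @property
    def confidence_fraction(self) -> Fraction:
        return as_fraction(self.min_confidence)


@dataclass(frozen=True)
class AssociationRule:
    """A ⇒ C with exact metrics relative to the mined group database."""

    antecedent: frozenset[str]
    consequent: str
    count: int            # co-occurrences of A ∪ {C}
    support: Fraction     # count / group N
    confidence: Fraction  # count / count(A)

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise RuleError("empty antecedent")
        if self.consequent in self.antecedent:
            raise RuleError("consequent inside antecedent")

    @property
    def key(self) -> tuple[tuple[str, ...], str]:
        return (tuple(sorted(self.antecedent)), self.consequent)

    def render_antecedent(self) -> str:
        return "; ".join(sorted(self.antecedent))

    def __str__(self) -> str:
        return (f"{self.render_antecedent()} => {self.consequent} "
                f"(support={round2(self.support):.2f}, "
                f"confidence={round2(self.confidence):.2f})")


@dataclass
class RuleSet:
    """Rules in canonical order with their mining provenance.

    Canonical order: descending support, then ascending rendered
    antecedent. Provenance records algorithm, dataset and group labels and
    the thresholds, so rule sets from different runs refuse comparison.
    """

    rules: list[AssociationRule]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.rules]
        if len(set(keys)) != len(keys):
            raise RuleError("duplicate (antecedent, consequent) pair in rule set")
        self.rules = sorted(
            self.rules, key=lambda r: (-r.support, r.render_antecedent())
        )

    def __len__(self) -> int:
        return len(self.rules)

    def by_key(self) -> dict[tuple, AssociationRule]:
        return {r.key: r for r in self.rules}

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["group", "antecedents", "consequent", "support",
                    "confidence", "count"])
        group = self.provenance.get("group", "")
        for r in self.rules:
            w.writerow([group, r.render_antecedent(), r.consequent,
                        f"{round2(r.support):.2f}",
                        f"{round2(r.confidence):.2f}", r.count])
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps({
            "provenance": self.provenance,
            "rules": [
                {
                    "antecedent": sorted(r.antecedent),
                    "consequent": r.consequent,
                    "count": r.count,
                    "support": [r.support.numerator, r.support.denominator],
                    "confidence": [r.confidence.numerator,
                                   r.confidence.denominator],
                }
                for r in self.rules
            ],
        }, indent=2, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        obj = json.loads(text)
        rules = [
            AssociationRule(
                antecedent=frozenset(r["antecedent"]),
                consequent=r["consequent"],
                count=r["count"],
                support=Fraction(*r["support"]),
                confidence=Fraction(*r["confidence"]),
            )
            for r in obj["rules"]
        ]
        return cls(rules=rules, provenance=obj.get("provenance", {}))


def generate_class_rules(
    group_db: TransactionDB,
    class_item: str,
    frequent: FrequentItemsets,
    thresholds: Thresholds,
    max_antecedent: int | None = None,
    provenance: Mapping | None = None,
) -> RuleSet:
    """Turn a group's frequent itemsets into class-targeted rules.

    Every frequent itemset not containing the class item becomes the
    antecedent of one candidate rule A ⇒ class; rules failing either
    threshold are dropped. The group must be class-stratified (the class
    item in every transaction), which this function verifies.
    """
    if any(class_item not in t for t in group_db.itemsets()):
        raise RuleError(
            f"stratification violated: {class_item!r} absent from some transaction"
        )
    min_sup = thresholds.support_fraction
    min_conf = thresholds.confidence_fraction
    n = group_db.N
    rules: list[AssociationRule] = []
    for itemset, sup in frequent.items():
        if class_item in itemset:
            continue  # the A∪C itemset; its A-only twin generates the rule
        antecedent = itemset
        if max_antecedent is not None and len(antecedent) > max_antecedent:
            continue
        count_a = sup.count
        count_ac = sum(
            1 for t in group_db.itemsets() if antecedent <= t and class_item in t
        )
        if count_a == 0:
            continue
        support = Fraction(count_ac, n)
        confidence = Fraction(count_ac, count_a)
        if support >= min_sup and confidence >= min_conf:
            rules.append(AssociationRule(
                antecedent=antecedent, consequent=class_item,
                count=count_ac, support=support, confidence=confidence,
            ))
    prov = dict(provenance or {})
    prov.setdefault("thresholds", {
        "min_support": str(thresholds.support_fraction),
        "min_confidence": str(thresholds.confidence_fraction),
    })
    return RuleSet(rules=rules, provenance=prov)


def categorize_rule(rule: AssociationRule, thresholds: Thresholds) -> str:
    """``frequent`` iff both metrics meet their thresholds (inclusive);
    otherwise ``infrequent`` — including low-support/high-confidence."""
    ok = (rule.support >= thresholds.support_fraction
          and rule.confidence >= thresholds.confidence_fraction)
    return "frequent" if ok else "infrequent"
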