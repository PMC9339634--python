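"""Consensus between independently mined rule sets.

Both miners compute exact integer counts over the same database, so on a
correct implementation the intersection ("mutual rules") equals either
input and both only-sets are empty — any asymmetry is a mining bug
detector, which is exactly the diagnostic value of this stage. The metric
tolerance therefore defaults to strict equality; a nonzero tolerance is
only meaningful when comparing rule sets from approximate or external
sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
import json

from .rules import AssociationRule, RuleError, RuleSet, round2


class ConsensusError(Exception):
    """Rule sets with mismatched provenance refuse comparison."""


@dataclass
class ConsensusReport:
    """Mutual and algorithm-exclusive rules, plus metric discrepancies for
    keys present in both sets whose metrics disagree beyond tolerance."""

    mutual: RuleSet
    only_first: RuleSet
    only_second: RuleSet
    metric_discrepancies: list[tuple[tuple, Fraction, Fraction]] = field(
        default_factory=list
    )

    @property
    def is_clean(self) -> bool:
        return (not self.only_first.rules and not self.only_second.rules
                and not self.metric_discrepancies)

    def to_json(self) -> str:
        return json.dumps({
            "mutual": json.loads(self.mutual.to_json()),
            "only_first": json.loads(self.only_first.to_json()),
            "only_second": json.loads(self.only_second.to_json()),
            "metric_discrepancies": [
                {"antecedent": list(key[0]), "consequent": key[1],
                 "support_delta": float(ds), "confidence_delta": float(dc)}
                for key, ds, dc in self.metric_discrepancies
            ],
        }, indent=2, ensure_ascii=False)

    def to_csv(self) -> str:
        lines = ["section,antecedents,consequent,support,confidence,count"]
        for section, rs in (("mutual", self.mutual),
                            ("only_first", self.only_first),
                            ("only_second", self.only_second)):
            for r in rs.rules:
                lines.append(
                    f"{section},{r.render_antecedent()},{r.consequent},"
                    f"{round2(r.support):.2f},{round2(r.confidence):.2f},{r.count}"
                )
        return "\n".join(lines) + "\n"


_COMPARABLE_KEYS = ("dataset", "group", "thresholds")


def mutual_rules(
    a: RuleSet,
    b: RuleSet,
    metric_tolerance: float | Fraction = 0,
) -> ConsensusReport:
    """Intersect two rule sets keyed by (antecedent, consequent).

    Rules present in both inputs land in ``mutual``; when their metrics
    disagree beyond ``metric_tolerance`` the discrepancy is recorded (never
    silently merged) and the first input's metrics are reported.
    Swapping the inputs swaps the only-sets and preserves the mutual keys.
    """
    for key in _COMPARABLE_KEYS:
        if a.provenance.get(key) != b.provenance.get(key):
            raise ConsensusError(
                f"provenance mismatch on {key!r}: "
                f"{a.provenance.get(key)!r} vs {b.provenance.get(key)!r}"
            )
    tol = Fraction(metric_tolerance) if not isinstance(metric_tolerance, Fraction) \
        else metric_tolerance
    a_rules = a.by_key()
    b_rules = b.by_key()
    mutual, discrepancies = [], []
    for key in a_rules.keys() & b_rules.keys():
        ra, rb = a_rules[key], b_rules[key]
        ds = abs(ra.support - rb.support)
        dc = abs(ra.confidence - rb.confidence)
        if ds > tol or dc > tol:
            discrepancies.append((key, ds, dc))
        mutual.append(ra)
    prov = {k: a.provenance.get(k) for k in _COMPARABLE_KEYS}
    prov["algorithm"] = "consensus({}, {})".format(
        a.provenance.get("algorithm"), b.provenance.get("algorithm"))
    return ConsensusReport(
        mutual=RuleSet(mutual, provenance=prov),
        only_first=RuleSet(
            [a_rules[k] for k in a_rules.keys() - b_rules.keys()],
            provenance=dict(a.provenance),
        ),
        only_second=RuleSet(
            [b_rules[k] for k in b_rules.keys() - a_rules.keys()],
            provenance=dict(b.provenance),
        ),
        metric_discrepancies=sorted(discrepancies, key=lambda d: d[0]),
    )
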