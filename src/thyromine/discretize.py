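"""Encoding cleaned records as categorical transactions.

Every attribute of a cleaned record is mapped to a single *item* — the
string ``"attribute=level"`` — by a per-attribute discretization rule:

* ``Categorical``: the value is used verbatim (optionally normalized
  through a label map, e.g. ``{f,t} -> {False,True}``).
* ``NormalRange(lo, hi)``: numeric values inside the closed interval
  [lo, hi] become ``Normal``, everything else ``Abnormal``. This encodes
  laboratory reference ranges.
* ``Bins``: ordered, non-overlapping labeled intervals; each interval is
  half-open [lo, hi) except the last, which is closed so the topmost
  boundary value still maps to a bin. Values outside all bins raise.
* ``BinaryThreshold(cut)``: numeric values split into ``≤cut`` / ``>cut``.

A transaction is the set of items of one record, exactly one item per
attribute; a :class:`TransactionDB` is the ordered collection feeding the
frequent-itemset miners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

from .ingest import MISSING, RawTable


class DiscretizationError(Exception):
    """A value cannot be mapped under the configured rule."""


class Item(NamedTuple):
    """A categorical atom: one attribute at one level."""

    attribute: str
    level: str

    def render(self) -> str:
        return f"{self.attribute}={self.level}"

    @classmethod
    def parse(cls, rendered: str) -> "Item":
        attr, _, level = rendered.partition("=")
        if not attr or not level:
            raise ValueError(f"not a rendered item: {rendered!r}")
        return cls(attr, level)


def render_item(attribute: str, level: str) -> str:
    """Render ``attribute=level``; attribute names must not contain '='."""
    if "=" in attribute:
        raise DiscretizationError(f"attribute name contains '=': {attribute!r}")
    return f"{attribute}={level}"


# -- rule kinds -------------------------------------------------------------

#: Normalization applied by boolean-ish categorical rules.
BOOLEAN_LEVELS: dict[str, str] = {
    "f": "False", "t": "True", "0": "False", "1": "True",
    "n": "False", "y": "True", "no": "False", "yes": "True",
    "false": "False", "true": "True",
}


@dataclass(frozen=True)
class Categorical:
    """Pass the value through, optionally normalizing labels.

    ``levels`` restricts legal values (after normalization); ``None``
    accepts anything.
    """

    mapping: Mapping[str, str] | None = None
    levels: tuple[str, ...] | None = None

    def apply(self, value: str) -> str:
        level = value
        if self.mapping is not None:
            level = self.mapping.get(value, self.mapping.get(value.lower(), value))
        if self.levels is not None and level not in self.levels:
            raise DiscretizationError(f"level {value!r} not in {self.levels}")
        return level


def boolean_rule() -> Categorical:
    """Categorical rule normalizing {f,t}/{0,1}/{N,Y} spellings to
    {False, True}."""
    return Categorical(mapping=BOOLEAN_LEVELS, levels=("False", "True"))


@dataclass(frozen=True)
class NormalRange:
    """Closed reference interval: value in [lo, hi] -> Normal, else Abnormal."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise DiscretizationError(f"normal range needs lo < hi, got {self}")

    def apply(self, value: str) -> str:
        x = _as_number(value)
        return "Normal" if self.lo <= x <= self.hi else "Abnormal"


@dataclass(frozen=True)
class Bins:
    """Ordered labeled intervals [lo, hi); the last interval is closed."""

    bins: tuple[tuple[str, float, float], ...]  # (label, lo, hi)

    def __post_init__(self) -> None:
        for (l1, lo1, hi1), (l2, lo2, hi2) in zip(self.bins, self.bins[1:]):
            if hi1 > lo2:
                raise DiscretizationError(f"bins overlap: {l1} and {l2}")
        for label, lo, hi in self.bins:
            if not lo < hi:
                raise DiscretizationError(f"empty bin {label}: [{lo}, {hi})")

    def apply(self, value: str) -> str:
        x = _as_number(value)
        last = len(self.bins) - 1
        for i, (label, lo, hi) in enumerate(self.bins):
            if lo <= x < hi or (i == last and x == hi):
                return label
        raise DiscretizationError(f"value {value!r} outside all bins")


@dataclass(frozen=True)
class BinaryThreshold:
    """Numeric split at ``cut``: levels ``≤cut`` and ``>cut``."""

    cut: float
    le_label: str | None = None
    gt_label: str | None = None

    def apply(self, value: str) -> str:
        x = _as_number(value)
        cut_s = f"{self.cut:g}"
        if x <= self.cut:
            return self.le_label if self.le_label is not None else f"≤{cut_s}"
        return self.gt_label if self.gt_label is not None else f">{cut_s}"


Rule = Categorical | NormalRange | Bins | BinaryThreshold


def _as_number(value: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise DiscretizationError(f"non-numeric value {value!r} under numeric rule")


@dataclass
class DiscretizationSpec:
    """Per-attribute discretization rules.

    ``on_out_of_bin='raise'`` surfaces out-of-range values (the default);
    ``'drop'`` silently removes the offending record during encoding.
    """

    rules: dict[str, Rule]
    on_out_of_bin: str = "raise"

    def rule_for(self, attr: str) -> Rule:
        if attr not in self.rules:
            raise DiscretizationError(f"no discretization rule for {attr!r}")
        return self.rules[attr]


def discretize_value(attr: str, value: str, spec: DiscretizationSpec) -> Item:
    """Map one non-missing raw value to its item under ``spec``."""
    if value == MISSING:
        raise DiscretizationError(f"missing value reached discretizer for {attr!r}")
    rule = spec.rule_for(attr)
    try:
        level = rule.apply(value)
    except DiscretizationError as exc:
        raise DiscretizationError(f"{attr}: {exc}") from exc
    return Item(attr, level)


# -- transactions -----------------------------------------------------------


@dataclass(frozen=True)
class Transaction:
    """One encoded record: a set of rendered items, one per attribute.

    ``class_item`` is set for clinical transactions (and must be among the
    items); generic transaction databases without a class column leave it
    ``None``.
    """

    items: frozenset[str]
    class_item: str | None = None

    def __post_init__(self) -> None:
        attrs = [Item.parse(i).attribute for i in self.items]
        if len(set(attrs)) != len(attrs):
            raise DiscretizationError("two items share an attribute")
        if self.class_item is not None and self.class_item not in self.items:
            raise DiscretizationError("class_item not among items")


@dataclass
class TransactionDB:
    """Ordered transaction database T = {X_1, ..., X_N}."""

    transactions: list[Transaction]
    label: str = ""

    @property
    def N(self) -> int:
        return len(self.transactions)

    @property
    def item_universe(self) -> frozenset[str]:
        u: set[str] = set()
        for t in self.transactions:
            u |= t.items
        return frozenset(u)

    def itemsets(self) -> list[frozenset[str]]:
        return [t.items for t in self.transactions]

    @classmethod
    def from_itemsets(cls, itemsets, label: str = "") -> "TransactionDB":
        """Build a class-free database from raw itemset collections."""
        return cls(
            transactions=[Transaction(frozenset(map(str, s))) for s in itemsets],
            label=label,
        )


def encode_transactions(
    raw: RawTable, spec: DiscretizationSpec, class_attr: str
) -> TransactionDB:
    """Encode every cleaned record as one transaction.

    With ``spec.on_out_of_bin == 'drop'``, records whose numeric values fall
    outside every bin are removed (their count is recoverable as the
    difference in N); otherwise such records raise with their index.
    """
    if class_attr not in spec.rules:
        raise DiscretizationError(f"class attribute {class_attr!r} has no rule")
    transactions: list[Transaction] = []
    for idx, rec in enumerate(raw.records):
        try:
            items = frozenset(
                discretize_value(a, rec[a], spec).render()
                for a in raw.attribute_names
            )
            cls = discretize_value(class_attr, rec[class_attr], spec).render()
        except DiscretizationError as exc:
            if spec.on_out_of_bin == "drop":
                continue
            raise DiscretizationError(f"record {idx}: {exc}") from exc
        transactions.append(Transaction(items=items, class_item=cls))
    return TransactionDB(transactions=transactions, label=raw.source_label)


def split_by_class(db: TransactionDB, class_attr: str) -> dict[str, TransactionDB]:
    """Partition into one database per class level.

    Group sizes sum to ``db.N``; within each group the class item is, by
    construction, present in every transaction — the property that makes
    every mined class-rule's confidence exactly 1.
    """
    groups: dict[str, list[Transaction]] = {}
    for t in db.transactions:
        if t.class_item is None:
            raise DiscretizationError("transaction carries no class item")
        item = Item.parse(t.class_item)
        if item.attribute != class_attr:
            raise DiscretizationError(
                f"transaction class item {t.class_item!r} is not on {class_attr!r}"
            )
        groups.setdefault(item.level, []).append(t)
    return {
        level: TransactionDB(transactions=ts, label=f"{db.label}[{class_attr}={level}]")
        for level, ts in groups.items()
    }


# ---------------------------------------------------------------------------
# Bundled presets: the two study datasets' schemes
# ---------------------------------------------------------------------------

#: Decade age bins 20-80 used by the Dataset-I scheme.
AGE_BINS = Bins(bins=tuple(
    (f"{lo}-{lo + 10}", float(lo), float(lo + 10)) for lo in range(20, 80, 10)
))


def table1_spec(on_out_of_bin: str = "raise") -> DiscretizationSpec:
    """Dataset-I scheme: decade age bins, booleans, and thyroid-lab
    reference ranges (TSH 0.27–4.2, T3 1.3–3.1, TT4 62–164, T4U 0.7–1.8,
    FTI 53–142; all closed intervals)."""
    rules: dict[str, Rule] = {
        "Age": AGE_BINS,
        "Sex": Categorical(levels=("M", "F")),
        "TSH": NormalRange(0.27, 4.2),
        "T3": NormalRange(1.3, 3.1),
        "TT4": NormalRange(62, 164),
        "T4U": NormalRange(0.7, 1.8),
        "FTI": NormalRange(53, 142),
        "Class": Categorical(
            mapping={"negative": "Negative", "sick": "Positive",
                     "Negative": "Negative", "Positive": "Positive"},
            levels=("Negative", "Positive"),
        ),
    }
    for attr in ("On_thyroxine", "On_antithyroid_med", "Sick", "Pregnant",
                 "Thyroid_surgery", "I131", "Query_hypothyroid",
                 "Query_hyperthyroid", "Lithium", "Goiter", "Tumor",
                 "Hypopituitary", "Psych"):
        rules[attr] = boolean_rule()
    return DiscretizationSpec(rules=rules, on_out_of_bin=on_out_of_bin)


def table2_spec(on_out_of_bin: str = "raise") -> DiscretizationSpec:
    """Dataset-II scheme: age split at 50, gender, and boolean
    comorbidity/status attributes."""
    rules: dict[str, Rule] = {
        "Age": BinaryThreshold(50.0, le_label="≤50", gt_label=">50"),
        "Gender": Categorical(
            mapping={"Male": "M", "Fmale": "F", "Female": "F", "M": "M", "F": "F"},
            levels=("M", "F"),
        ),
        "CAD": Categorical(
            mapping={"Cad": "True", "Normal": "False", **BOOLEAN_LEVELS},
            levels=("False", "True"),
        ),
        "Class": Categorical(
            mapping={"N": "Negative", "Y": "Positive", "0": "Negative",
                     "1": "Positive", "Negative": "Negative",
                     "Positive": "Positive"},
            levels=("Negative", "Positive"),
        ),
    }
    for attr in ("Diabetes_mellitus", "Hypertension", "Current_smoker",
                 "Ex_smoker", "Obesity", "CRF", "CVA", "AD", "Edema",
                 "LR", "Dyspnea"):
        rules[attr] = boolean_rule()
    return DiscretizationSpec(rules=rules, on_out_of_bin=on_out_of_bin)


PRESET_SPECS = {"dataset1": table1_spec, "dataset2": table2_spec}
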