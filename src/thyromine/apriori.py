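"""Level-wise (Apriori) frequent-itemset mining.

Classic bottom-up search: count single items, keep those meeting the
minimum support, then repeatedly join frequent k-itemsets sharing a
(k-1)-prefix into (k+1)-candidates, prune candidates with an infrequent
k-subset, and count the survivors against the database. Anti-monotonicity
of support guarantees the join+prune enumeration loses nothing.

Support thresholds are handled without floating-point comparisons: a
decimal threshold s over a database of N transactions keeps an itemset iff
``count >= ceil(s * N)`` computed in exact rational arithmetic, with the
decimal literal taken at face value (0.6 means 3/5). An itemset counted in
exactly s·N transactions therefore survives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Mapping

from .discretize import TransactionDB


class MiningError(Exception):
    """Invalid mining configuration (e.g. non-positive support threshold)."""


@dataclass(frozen=True)
class ItemsetSupport:
    """An itemset with its exact occurrence count and support fraction."""

    items: frozenset[str]
    count: int
    support: Fraction

    def __post_init__(self) -> None:
        if not self.items:
            raise MiningError("empty itemset")

    @property
    def support_float(self) -> float:
        return float(self.support)


FrequentItemsets = dict[frozenset, ItemsetSupport]


def as_fraction(threshold: float | str | Fraction) -> Fraction:
    """Interpret a support/confidence threshold exactly.

    Floats are read as the decimal they print (``0.6`` -> 3/5), not as
    their binary expansion, so printed thresholds behave as written.
    """
    if isinstance(threshold, Fraction):
        return threshold
    if isinstance(threshold, float):
        return Fraction(repr(threshold))
    return Fraction(str(threshold))


def min_count_for(min_support: float | str | Fraction, n: int) -> int:
    """Smallest integer count c with c/n >= min_support; at least 1."""
    s = as_fraction(min_support)
    if s <= 0:
        raise MiningError(f"min_support must be positive, got {min_support}")
    if s > 1:
        raise MiningError(f"min_support must be <= 1, got {min_support}")
    return max(1, math.ceil(s * n))


def _count_itemsets(
    transactions: list[frozenset[str]], candidates: Iterable[frozenset[str]]
) -> dict[frozenset, int]:
    counts = {c: 0 for c in candidates}
    for t in transactions:
        for c in counts:
            if c <= t:
                counts[c] += 1
    return counts


def join_candidates(frequent_k: Iterable[frozenset]) -> set[frozenset]:
    """Join frequent k-itemsets into pruned (k+1)-candidates.

    Two k-sets sharing k-1 items (identical sorted prefix) join; any
    candidate with a k-subset missing from ``frequent_k`` is pruned.
    """
    fk = set(frequent_k)
    if not fk:
        return set()
    sizes = {len(s) for s in fk}
    if len(sizes) != 1:
        raise MiningError(f"mixed itemset sizes in join: {sorted(sizes)}")
    k = sizes.pop()
    # sorted-tuple prefix join for determinism
    sorted_sets = sorted(tuple(sorted(s)) for s in fk)
    out: set[frozenset] = set()
    for a, b in combinations(sorted_sets, 2):
        if a[: k - 1] == b[: k - 1]:
            cand = frozenset(a) | frozenset(b)
            if all(frozenset(sub) in fk for sub in combinations(sorted(cand), k)):
                out.add(cand)
    return out


def apriori_mine(
    db: TransactionDB,
    min_support: float | str | Fraction,
    max_len: int | None = None,
) -> FrequentItemsets:
    """Mine all itemsets with support >= ``min_support`` (inclusive).

    Returns a mapping itemset -> :class:`ItemsetSupport` with exact integer
    counts. The output is downward closed: every nonempty subset of a
    returned itemset is returned too. Independent of transaction and item
    order.
    """
    if db.N < 1:
        raise MiningError("empty database")
    transactions = db.itemsets()
    n = db.N
    minc = min_count_for(min_support, n)

    # level 1: direct item counting
    item_counts: dict[frozenset, int] = {}
    for t in transactions:
        for item in t:
            key = frozenset((item,))
            item_counts[key] = item_counts.get(key, 0) + 1
    frequent: FrequentItemsets = {
        s: ItemsetSupport(s, c, Fraction(c, n))
        for s, c in item_counts.items()
        if c >= minc
    }
    level = {s for s in frequent}
    k = 1
    while level and (max_len is None or k < max_len):
        candidates = join_candidates(level)
        if not candidates:
            break
        counts = _count_itemsets(transactions, candidates)
        level = set()
        for s, c in counts.items():
            if c >= minc:
                frequent[s] = ItemsetSupport(s, c, Fraction(c, n))
                level.add(s)
        k += 1
    return frequent
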