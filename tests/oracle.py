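"""Independent exhaustive frequent-itemset oracle.

Enumerates every nonempty itemset over the database's universe (feasible
for <= ~14 distinct items) and counts it against bitmask-encoded
transactions with numpy. Shares no code with the miners under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np


def oracle_min_count(min_support, n: int) -> int:
    """Smallest count c with c/n >= min_support, decimal-exact, >= 1."""
    s = Fraction(repr(min_support)) if isinstance(min_support, float) \
        else Fraction(str(min_support))
    return max(1, math.ceil(s * n))


def exhaustive_mine(itemsets: list[frozenset], min_support) -> dict[frozenset, int]:
    """All itemsets with count >= ceil(min_support * N), by brute force."""
    n = len(itemsets)
    universe = sorted(set().union(*itemsets)) if itemsets else []
    minc = oracle_min_count(min_support, n)
    bit = {item: 1 << i for i, item in enumerate(universe)}
    tmasks = np.array(
        [sum(bit[i] for i in t) for t in itemsets], dtype=np.int64
    )
    out: dict[frozenset, int] = {}
    for r in range(1, len(universe) + 1):
        for combo in combinations(universe, r):
            mask = np.int64(sum(bit[i] for i in combo))
            count = int(((tmasks & mask) == mask).sum())
            if count >= minc:
                out[frozenset(combo)] = count
    return out
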