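"""FP-Growth frequent-itemset mining.

The transaction database is compressed into an FP-tree: transactions are
rewritten with their frequent items in descending support order (ties
broken lexicographically on the rendered item string) and inserted as
prefix paths from a null root, merging shared prefixes and accumulating
per-node counts. A header table threads all tree nodes of each item.

Mining proceeds recursively: for each item in ascending header order, the
prefix paths above its nodes form the conditional pattern base, which is
rebuilt as a smaller conditional FP-tree and mined with the item appended
to the current suffix. No candidate generation is needed; the output
contract (itemsets with exact counts at an inclusive threshold) is
identical to the level-wise miner's, which is what makes the consensus
stage a meaningful integrity check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

from .apriori import FrequentItemsets, ItemsetSupport, MiningError, min_count_for
from .discretize import TransactionDB


class FPNode:
    """One FP-tree node; the root carries ``item=None`` and ``count=0``."""

    __slots__ = ("item", "count", "children", "parent", "next_same_item")

    def __init__(self, item: str | None, parent: "FPNode | None") -> None:
        self.item = item
        self.count = 0
        self.children: dict[str, FPNode] = {}
        self.parent = parent
        self.next_same_item: FPNode | None = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"FPNode({self.item!r}, count={self.count})"


@dataclass
class HeaderTable:
    """Items meeting min support, in the insertion order used for every
    transaction: descending total count, lexicographic tie-break."""

    entries: list[tuple[str, int]]  # (item, total count), sorted
    heads: dict[str, FPNode | None] = field(default_factory=dict)
    tails: dict[str, FPNode] = field(default_factory=dict, repr=False)

    def order(self) -> dict[str, int]:
        return {item: i for i, (item, _) in enumerate(self.entries)}

    def chain(self, item: str) -> Iterable[FPNode]:
        node = self.heads.get(item)
        while node is not None:
            yield node
            node = node.next_same_item

    def link(self, node: FPNode) -> None:
        assert node.item is not None
        if self.heads.get(node.item) is None:
            self.heads[node.item] = node
        else:
            self.tails[node.item].next_same_item = node
        self.tails[node.item] = node


def _build_tree_from_weighted(
    weighted: Iterable[tuple[frozenset[str], int]], minc: int
) -> tuple[FPNode, HeaderTable]:
    """Core construction shared by the top-level tree (weight 1 per
    transaction) and conditional trees (weights from pattern bases)."""
    weighted = list(weighted)
    totals: dict[str, int] = {}
    for items, w in weighted:
        for item in items:
            totals[item] = totals.get(item, 0) + w
    kept = {i: c for i, c in totals.items() if c >= minc}
    header = HeaderTable(
        entries=sorted(kept.items(), key=lambda e: (-e[1], e[0])),
        heads={i: None for i in kept},
    )
    order = header.order()
    root = FPNode(None, None)
    for items, w in weighted:
        path = sorted((i for i in items if i in kept), key=order.__getitem__)
        node = root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = FPNode(item, node)
                node.children[item] = child
                header.link(child)
            child.count += w
            node = child
    return root, header


def build_fptree(
    db: TransactionDB, min_support: float | str | Fraction
) -> tuple[FPNode, HeaderTable]:
    """Build the FP-tree of ``db`` at the given (inclusive) threshold.

    Infrequent items never enter the tree; for each frequent item the
    counts along its header chain sum to its database count.
    """
    minc = min_count_for(min_support, db.N)
    return _build_tree_from_weighted(((t, 1) for t in db.itemsets()), minc)


def _mine_tree(
    root: FPNode,
    header: HeaderTable,
    minc: int,
    suffix: frozenset[str],
    out: dict[frozenset, int],
    max_len: int | None,
) -> None:
    # ascending header order: least frequent suffix item first
    for item, total in reversed(header.entries):
        pattern = suffix | {item}
        out[pattern] = total
        if max_len is not None and len(pattern) >= max_len:
            continue
        # conditional pattern base: prefix paths above each node of `item`
        base: list[tuple[frozenset[str], int]] = []
        for node in header.chain(item):
            path: list[str] = []
            p = node.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                base.append((frozenset(path), node.count))
        if not base:
            continue
        croot, cheader = _build_tree_from_weighted(base, minc)
        if cheader.entries:
            _mine_tree(croot, cheader, minc, pattern, out, max_len)


def fpgrowth_mine(
    db: TransactionDB,
    min_support: float | str | Fraction,
    max_len: int | None = None,
) -> FrequentItemsets:
    """Mine all itemsets with support >= ``min_support``.

    Same output contract as :func:`thyromine.apriori.apriori_mine`: a
    mapping itemset -> exact count/support, downward closed.
    """
    if db.N < 1:
        raise MiningError("empty database")
    n = db.N
    minc = min_count_for(min_support, n)
    root, header = build_fptree(db, min_support)
    counts: dict[frozenset, int] = {}
    _mine_tree(root, header, minc, frozenset(), counts, max_len)
    return {
        s: ItemsetSupport(s, c, Fraction(c, n)) for s, c in counts.items()
    }


def dump_tree(root: FPNode, indent: int = 0) -> str:
    """Indented text rendering of an FP-tree, for fixtures and debugging."""
    lines = []
    label = "null" if root.item is None else f"{root.item}:{root.count}"
    lines.append("  " * indent + label)
    for item in sorted(root.children):
        lines.append(dump_tree(root.children[item], indent + 1))
    return "\n".join(lines)
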