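"""Restructuring the assigned tree into a hierarchically complete one.

After rank assignment, four steps make every root-to-leaf lineage carry
exactly one node per rank level:

* unranked taxa that received no rank are **deleted**, their children
  re-attached to the nearest retained ancestor (the original tree is kept
  around for the ``tree_all`` view);
* assigned taxa become **type-1** nodes and are renamed
  ``<abbrev>_<original name>``;
* level gaps between consecutive retained nodes are filled with chains of
  **type-2** nodes named ``<abbrev>_of_<name of the ranked child end>``;
* leaves above the bottom level grow chains of **type-3** nodes named
  ``<abbrev>_in_<leaf name>`` down to level N.

Every node carries a code ``<txid>.DDD``: ``000`` for originally ranked
taxa, otherwise two digits of rank level plus one digit of node type
(``6072.031`` = txid 6072, level 3, type 1).  Codes are strings throughout —
parsing them as floats would destroy the suffix.

The original root (txid == parent txid, unranked in NCBI) is kept as the
completed tree's root at level 0 with code ``<txid>.000``; lineages start at
its level-1 children.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .rank_assignment import Assignment, assign_all
from .rank_model import RankTable, abbreviation_for
from .taxdump_io import Taxonomy

__all__ = [
    "CompletedNode",
    "CompletedTree",
    "PrunedTree",
    "LineageRow",
    "make_code",
    "make_name",
    "delete_unassigned",
    "interpolate_missing",
    "extend_leaves",
    "complete",
    "lineage_row",
]


@dataclass(frozen=True)
class CompletedNode:
    code: str
    source_txid: int
    level: int
    node_type: int  # 0 original rank, 1 assigned, 2 interpolated, 3 appended
    display_name: str
    source_name: str  # original NCBI name the node derives from


@dataclass
class CompletedTree:
    nodes: dict[str, CompletedNode] = field(default_factory=dict)
    parent: dict[str, str] = field(default_factory=dict)
    children: dict[str, list[str]] = field(default_factory=dict)
    root: str = ""
    #: retained original txid -> its code
    code_of_txid: dict[int, str] = field(default_factory=dict)

    def add(self, node: CompletedNode, parent_code: str | None) -> None:
        if node.code in self.nodes:
            raise ValueError(f"duplicate code {node.code}")
        self.nodes[node.code] = node
        self.children.setdefault(node.code, [])
        if parent_code is None:
            self.root = node.code
        else:
            self.parent[node.code] = parent_code
            self.children.setdefault(parent_code, []).append(node.code)

    def path_to_root(self, code: str) -> list[str]:
        """Codes from ``code`` up to (and including) the root."""
        path = [code]
        while path[-1] != self.root:
            path.append(self.parent[path[-1]])
        return path

    def leaves(self) -> list[str]:
        return [c for c, kids in self.children.items() if not kids]

    def edges(self) -> list[tuple[str, str]]:
        """(parent_code, child_code) pairs, sorted for deterministic output."""
        return sorted((p, c) for c, p in self.parent.items())


@dataclass
class PrunedTree:
    """The retained (ranked or assigned) nodes with re-attached parents."""

    taxonomy: Taxonomy
    assignment: Assignment
    level: dict[int, int]            # retained txid -> rank level (root: 0)
    parent: dict[int, int]           # retained txid -> nearest retained ancestor
    children: dict[int, list[int]]   # sorted ascending by txid
    root_txid: int

    def retained(self, txid: int) -> bool:
        return txid in self.level


def make_code(source_txid: int, level: int, node_type: int) -> str:
    """Mint the ``<txid>.DDD`` identifier code (always a string)."""
    if node_type == 0:
        return f"{source_txid}.000"
    if node_type not in (1, 2, 3):
        raise ValueError(f"node type must be 0..3, got {node_type}")
    if not 1 <= level <= 99:
        raise ValueError(f"rank level {level} out of range for a 2-digit code")
    return f"{source_txid}.{level:02d}{node_type}"


def make_name(
    node_type: int,
    level: int,
    base_name: str,
    table: RankTable,
    separator: str = "_",
    display: bool = False,
) -> str:
    """Name for a created/modified node.

    type 1 -> ``<abbrev>_<base>``, type 2 -> ``<abbrev>_of_<base>``,
    type 3 -> ``<abbrev>_in_<base>``.  ``display=True`` joins with spaces
    ("spPhy of E_5") instead of the separator.
    """
    if not base_name:
        raise ValueError("base_name must be non-empty")
    sep = " " if display else separator
    abbrev = abbreviation_for(level, table)
    if node_type == 1:
        return f"{abbrev}{sep}{base_name}"
    if node_type == 2:
        return f"{abbrev}{sep}of{sep}{base_name}"
    if node_type == 3:
        return f"{abbrev}{sep}in{sep}{base_name}"
    raise ValueError(f"no name grammar for node type {node_type}")


def delete_unassigned(t: Taxonomy, a: Assignment) -> PrunedTree:
    """Drop unranked taxa that received no rank; re-attach their children to
    the nearest retained ancestor.  The root is always retained (level 0)."""
    level: dict[int, int] = {t.root_txid: 0}
    for v, node in t.nodes.items():
        if node.rank_level is not None:
            level[v] = node.rank_level
    for v, lvl in a.assigned.items():
        level[v] = lvl

    parent: dict[int, int] = {}
    children: dict[int, list[int]] = {v: [] for v in level}
    # top-down: nearest retained ancestor is already resolved for the parent
    anchor: dict[int, int] = {t.root_txid: t.root_txid}
    for v in t.depth_order():
        if v == t.root_txid:
            continue
        p_anchor = anchor[t.nodes[v].parent_txid]
        if v in level:
            anchor[v] = v
            parent[v] = p_anchor
            children[p_anchor].append(v)
        else:
            anchor[v] = p_anchor
    for kids in children.values():
        kids.sort()
    return PrunedTree(t, a, level, parent, children, t.root_txid)


def _base_name(t: Taxonomy, txid: int) -> str:
    return t.nodes[txid].scientific_name


def interpolate_missing(
    pruned: PrunedTree, table: RankTable, separator: str = "_", display: bool = False
) -> CompletedTree:
    """Build the completed tree from the pruned one, inserting type-2 chains
    wherever a parent/child edge skips levels.  Each created node is named
    after the original (unprefixed) name of the ranked child end of the edge
    and coded with that child's txid."""
    t = pruned.taxonomy
    ct = CompletedTree()
    root = pruned.root_txid
    root_name = _base_name(t, root)
    ct.add(
        CompletedNode(make_code(root, 0, 0), root, 0, 0, root_name, root_name),
        None,
    )
    ct.code_of_txid[root] = ct.root

    order = [root]
    i = 0
    while i < len(order):
        v = order[i]
        i += 1
        for c in pruned.children[v]:
            order.append(c)
            parent_code = ct.code_of_txid[v]
            lo, hi = pruned.level[v], pruned.level[c]
            for gap_level in range(lo + 1, hi):
                node = CompletedNode(
                    make_code(c, gap_level, 2),
                    c,
                    gap_level,
                    2,
                    make_name(2, gap_level, _base_name(t, c), table, separator, display),
                    _base_name(t, c),
                )
                ct.add(node, parent_code)
                parent_code = node.code
            if c in pruned.assignment.assigned:
                child_node = CompletedNode(
                    make_code(c, hi, 1),
                    c,
                    hi,
                    1,
                    make_name(1, hi, _base_name(t, c), table, separator, display),
                    _base_name(t, c),
                )
            else:
                child_node = CompletedNode(
                    make_code(c, hi, 0), c, hi, 0, _base_name(t, c), _base_name(t, c)
                )
            ct.add(child_node, parent_code)
            ct.code_of_txid[c] = child_node.code
    return ct


def extend_leaves(
    ct: CompletedTree, table: RankTable, separator: str = "_", display: bool = False
) -> CompletedTree:
    """Append type-3 chains below every leaf sitting above the bottom level,
    named after the leaf and coded with its txid."""
    n = table.n
    for leaf_code in ct.leaves():
        leaf = ct.nodes[leaf_code]
        parent_code = leaf_code
        base = leaf.source_name
        for lvl in range(leaf.level + 1, n + 1):
            node = CompletedNode(
                make_code(leaf.source_txid, lvl, 3),
                leaf.source_txid,
                lvl,
                3,
                make_name(3, lvl, base, table, separator, display),
                base,
            )
            ct.add(node, parent_code)
            parent_code = node.code
    return ct


def complete(
    t: Taxonomy,
    table: RankTable,
    separator: str = "_",
    display: bool = False,
    include_unclassified: bool = False,
    assignment: Assignment | None = None,
) -> tuple[CompletedTree, PrunedTree]:
    """Full pipeline: assign ranks, delete the unassignable, interpolate
    type-2 chains, append type-3 chains."""
    if assignment is None:
        assignment = assign_all(t, table, include_unclassified=include_unclassified)
    pruned = delete_unassigned(t, assignment)
    ct = interpolate_missing(pruned, table, separator, display)
    extend_leaves(ct, table, separator, display)
    return ct, pruned


@dataclass(frozen=True)
class LineageRow:
    """One node per rank level for a txid: N codes and N display names."""

    txid: int
    codes: tuple[str, ...]
    names: tuple[str, ...]


def lineage_row(
    ct: CompletedTree,
    t: Taxonomy,
    txid: int,
    table: RankTable,
    separator: str = "_",
    display: bool = False,
    resolve_deleted: bool = True,
) -> LineageRow:
    """The N-column lineage of ``txid``.

    Levels above the taxon come from the completed tree.  For an internal
    taxon at level k the columns k+1..N are *virtual* type-3 entries
    ``<abbrev>_in_<name>`` coded from that txid — row-level constructs, not
    tree nodes (a leaf's entries coincide with its real type-3 chain).
    Deleted unranked taxa resolve to their nearest retained ancestor's row.
    """
    if txid not in t.nodes:
        raise KeyError(f"unknown txid {txid}")
    v = txid
    while v not in ct.code_of_txid:
        if not resolve_deleted:
            raise KeyError(f"txid {txid} was deleted from the completed tree")
        v = t.nodes[v].parent_txid
    code = ct.code_of_txid[v]
    n = table.n
    codes: list[str] = [""] * n
    names: list[str] = [""] * n
    for c in ct.path_to_root(code):
        node = ct.nodes[c]
        if node.level >= 1:
            codes[node.level - 1] = node.code
            names[node.level - 1] = node.display_name
    anchor = ct.nodes[code]
    base = anchor.source_name
    for lvl in range(anchor.level + 1, n + 1):
        codes[lvl - 1] = make_code(anchor.source_txid, lvl, 3)
        names[lvl - 1] = make_name(3, lvl, base, table, separator, display)
    return LineageRow(txid, tuple(codes), tuple(names))
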