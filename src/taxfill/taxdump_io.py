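"""Reading and writing NCBI taxdump-dialect files.

The taxdump dialect separates fields with ``<TAB>|<TAB>`` and terminates each
record with ``<TAB>|``.  Only ``nodes.dmp`` (txid, parent txid, rank name,
further columns ignored) and ``names.dmp`` (txid, name, unique name, name
class) are consumed; merged/deleted-node files are out of scope.

Rank names found in the configured :class:`~taxfill.rank_model.RankTable`
map to a rank level; everything else — ``no rank``, ``clade`` and any rank
vocabulary NCBI adds later — is treated as unranked.

"Unclassified" taxa (names containing *unpublished*, *unidentified*,
*unassigned*, *environmental sample(s)*, *incertae sedis* or *unclassified*)
are flagged: their descendants are not subjects for rank assignment, although
the flagged node itself still is.
"""

from __future__ import annotations

import tarfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from .rank_model import RankTable

__all__ = [
    "TaxNode",
    "Taxonomy",
    "TaxdumpError",
    "parse_taxdump",
    "load_taxdump",
    "write_taxdump",
    "is_unclassified_name",
    "flag_unclassified_subtrees",
    "leaf_txids",
]

FIELD_SEP = "\t|\t"
RECORD_END = "\t|"

#: Name fragments marking a taxon as an unclassified entry.  "environmental
#: sample" covers the plural; "unclassified" is an extension to the core list
#: (switchable via ``extra_terms`` of :func:`is_unclassified_name`).
UNCLASSIFIED_TERMS = (
    "unpublished",
    "unidentified",
    "unassigned",
    "environmental sample",
    "incertae sedis",
)
EXTRA_UNCLASSIFIED_TERMS = ("unclassified",)


class TaxdumpError(ValueError):
    """Malformed taxdump input (parse errors carry the offending line)."""


@dataclass
class TaxNode:
    txid: int
    parent_txid: int
    scientific_name: str = ""
    common_name: str | None = None
    rank_level: int | None = None
    rank_name: str = "no rank"
    is_unclassified: bool = False
    is_under_unclassified: bool = False

    @property
    def is_ranked(self) -> bool:
        return self.rank_level is not None


@dataclass
class Taxonomy:
    """A rooted taxonomy tree.

    ``children`` lists are kept sorted ascending by txid — the determinism
    contract every downstream traversal relies on.
    """

    nodes: dict[int, TaxNode] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)
    root_txid: int = 0

    def __len__(self) -> int:
        return len(self.nodes)

    def ancestors(self, txid: int) -> Iterator[int]:
        """Proper ancestors of ``txid``, nearest first, root last."""
        node = self.nodes[txid]
        while node.txid != self.root_txid:
            node = self.nodes[node.parent_txid]
            yield node.txid

    def subtree(self, txid: int) -> Iterator[int]:
        """``txid`` and all its descendants, depth-first, children by txid."""
        stack = [txid]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(reversed(self.children.get(v, ())))

    def depth_order(self) -> list[int]:
        """All txids in breadth-first order from the root (siblings by txid)."""
        order: list[int] = []
        frontier = [self.root_txid]
        while frontier:
            order.extend(frontier)
            nxt: list[int] = []
            for v in frontier:
                nxt.extend(self.children.get(v, ()))
            frontier = nxt
        return order

    def edge_set(self) -> set[tuple[int, int]]:
        """(parent, child) pairs, root self-loop excluded."""
        return {
            (n.parent_txid, n.txid)
            for n in self.nodes.values()
            if n.txid != self.root_txid
        }


def _records(text: str, what: str) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.endswith(RECORD_END):
            raise TaxdumpError(
                f"{what} line {lineno}: record does not end with <TAB>|"
            )
        yield lineno, line[: -len(RECORD_END)].split(FIELD_SEP)


def is_unclassified_name(name: str, extra_terms: bool = True) -> bool:
    """True if ``name`` marks an unclassified entry (case-insensitive
    substring match against the term list)."""
    low = name.casefold()
    terms = UNCLASSIFIED_TERMS + (EXTRA_UNCLASSIFIED_TERMS if extra_terms else ())
    return any(t in low for t in terms)


def parse_taxdump(
    nodes_source: str,
    names_source: str,
    table: RankTable,
    extra_unclassified_terms: bool = True,
) -> Taxonomy:
    """Parse nodes.dmp / names.dmp text into a validated :class:`Taxonomy`.

    Validates: single root (txid == parent txid), all parent references
    resolve, no cycles, every node has a scientific name, and ranked nodes
    never sit at a level <= a ranked ancestor (a violated rank hierarchy is
    an input error, not something to repair silently).
    """
    t = Taxonomy()
    for lineno, fields in _records(nodes_source, "nodes.dmp"):
        if len(fields) < 3:
            raise TaxdumpError(
                f"nodes.dmp line {lineno}: expected >=3 fields, got {len(fields)}"
            )
        try:
            txid, parent = int(fields[0]), int(fields[1])
        except ValueError:
            raise TaxdumpError(
                f"nodes.dmp line {lineno}: non-numeric txid/parent"
            ) from None
        if txid in t.nodes:
            raise TaxdumpError(f"nodes.dmp line {lineno}: duplicate txid {txid}")
        rank_name = fields[2].strip()
        t.nodes[txid] = TaxNode(
            txid=txid,
            parent_txid=parent,
            rank_level=table.level_of(rank_name),
            rank_name=rank_name,
        )

    roots = [n.txid for n in t.nodes.values() if n.txid == n.parent_txid]
    if not roots:
        raise TaxdumpError("no root: nodes.dmp has no record with txid == parent")
    if len(roots) > 1:
        raise TaxdumpError(f"multiple roots: {roots}")
    t.root_txid = roots[0]

    for n in t.nodes.values():
        if n.parent_txid not in t.nodes:
            raise TaxdumpError(
                f"orphan parent reference: txid {n.txid} -> {n.parent_txid}"
            )
        t.children.setdefault(n.txid, [])
        if n.txid != t.root_txid:
            t.children.setdefault(n.parent_txid, []).append(n.txid)
    for kids in t.children.values():
        kids.sort()

    # connectivity == acyclicity here (|edges| = |nodes| - 1 by construction)
    reached = sum(1 for _ in t.subtree(t.root_txid))
    if reached != len(t.nodes):
        raise TaxdumpError(
            f"cycle detected: only {reached} of {len(t.nodes)} nodes reachable from root"
        )

    _read_names(names_source, t)
    for n in t.nodes.values():
        if not n.scientific_name:
            raise TaxdumpError(f"txid {n.txid} has no scientific name")

    _check_rank_hierarchy(t)
    flag_unclassified_subtrees(t, extra_terms=extra_unclassified_terms)
    return t


def _read_names(names_source: str, t: Taxonomy) -> None:
    genbank_common: dict[int, str] = {}
    plain_common: dict[int, str] = {}
    for lineno, fields in _records(names_source, "names.dmp"):
        if len(fields) < 4:
            raise TaxdumpError(
                f"names.dmp line {lineno}: expected 4 fields, got {len(fields)}"
            )
        try:
            txid = int(fields[0])
        except ValueError:
            raise TaxdumpError(f"names.dmp line {lineno}: non-numeric txid") from None
        if txid not in t.nodes:
            continue  # names for merged/removed taxa are harmless
        name, name_class = fields[1], fields[3].strip()
        if name_class == "scientific name":
            t.nodes[txid].scientific_name = name
        elif name_class == "genbank common name":
            genbank_common[txid] = name
        elif name_class == "common name":
            plain_common.setdefault(txid, name)
    for txid, node in t.nodes.items():
        node.common_name = genbank_common.get(txid, plain_common.get(txid))


def _check_rank_hierarchy(t: Taxonomy) -> None:
    # nearest ranked ancestor level, computed top-down
    nearest: dict[int, int] = {t.root_txid: 0}
    for v in t.depth_order():
        node = t.nodes[v]
        if v == t.root_txid:
            anc = 0
        else:
            anc = nearest[node.parent_txid]
        if node.rank_level is not None:
            if node.rank_level <= anc:
                raise TaxdumpError(
                    f"rank hierarchy violated: txid {v} has level "
                    f"{node.rank_level} under an ancestor of level {anc}"
                )
            nearest[v] = node.rank_level
        else:
            nearest[v] = anc


def flag_unclassified_subtrees(t: Taxonomy, extra_terms: bool = True) -> Taxonomy:
    """Set ``is_unclassified`` per node name and ``is_under_unclassified``
    for nodes with an unclassified *proper* ancestor."""
    for n in t.nodes.values():
        n.is_unclassified = is_unclassified_name(n.scientific_name, extra_terms)
    for v in t.depth_order():
        node = t.nodes[v]
        if v == t.root_txid:
            node.is_under_unclassified = False
            continue
        parent = t.nodes[node.parent_txid]
        node.is_under_unclassified = (
            parent.is_unclassified or parent.is_under_unclassified
        )
    return t


def leaf_txids(t: Taxonomy, exclude_unclassified: bool = False) -> set[int]:
    """Childless txids; optionally drop unclassified taxa and anything under
    an unclassified ancestor (the convention used for leaf statistics)."""
    leaves = {v for v, kids in t.children.items() if not kids}
    if exclude_unclassified:
        leaves = {
            v
            for v in leaves
            if not (t.nodes[v].is_unclassified or t.nodes[v].is_under_unclassified)
        }
    return leaves


def write_taxdump(t: Taxonomy) -> tuple[str, str]:
    """Serialize back to canonical nodes.dmp / names.dmp text (txids
    ascending, three node fields, scientific + common name records)."""
    nodes_lines = []
    names_lines = []
    for txid in sorted(t.nodes):
        n = t.nodes[txid]
        nodes_lines.append(
            f"{n.txid}{FIELD_SEP}{n.parent_txid}{FIELD_SEP}{n.rank_name}{RECORD_END}"
        )
        names_lines.append(
            f"{n.txid}{FIELD_SEP}{n.scientific_name}{FIELD_SEP}{FIELD_SEP}scientific name{RECORD_END}"
        )
        if n.common_name:
            names_lines.append(
                f"{n.txid}{FIELD_SEP}{n.common_name}{FIELD_SEP}{FIELD_SEP}genbank common name{RECORD_END}"
            )
    return "\n".join(nodes_lines) + "\n", "\n".join(names_lines) + "\n"


def load_taxdump(
    source: str | Path,
    table: RankTable,
    extra_unclassified_terms: bool = True,
) -> Taxonomy:
    """Load from a directory containing nodes.dmp/names.dmp or from a
    .tar.gz taxdump archive."""
    path = Path(source)
    if path.is_dir():
        nodes_text = (path / "nodes.dmp").read_text()
        names_text = (path / "names.dmp").read_text()
    elif tarfile.is_tarfile(path):
        with tarfile.open(path) as tar:
            nodes_text = _tar_member(tar, "nodes.dmp")
            names_text = _tar_member(tar, "names.dmp")
    else:
        raise TaxdumpError(f"{source}: not a taxdump directory or archive")
    return parse_taxdump(nodes_text, names_text, table, extra_unclassified_terms)


def _tar_member(tar: tarfile.TarFile, name: str) -> str:
    for member in tar.getmembers():
        if Path(member.name).name == name:
            f = tar.extractfile(member)
            if f is not None:
                return f.read().decode()
    raise TaxdumpError(f"archive does not contain {name}")
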