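"""Candidate ranks for unranked taxa.

An unranked node may only assume a rank level strictly between the lowest
rank found among its ancestors and the highest rank found among its
descendants; otherwise the rank hierarchy (levels strictly increasing from
root to tip) would break.  The open interval, minus the Species/Genus
restrictions below, is the node's *candidate set*.  It may be empty — a node
squeezed between consecutive levels can never be ranked.

Species/Genus restrictions: Species may be assigned only if some ancestor
carries the Genus rank *in the original database*; Genus only if some
descendant carries the original Species rank; neither may be assigned to an
unclassified entry (or anything below one).  Assignments made during a run
never satisfy these preconditions — only original ranks do.

:class:`CandidateStore` tracks candidate sets while the assignment engine
runs: an assignment at level L tightens the bounds of the node's relatives.
Because assignment only ever *adds* ranked levels, the cached
minimum-level-in-subtree values are maintained by a cheap walk to the root.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rank_model import RankTable
from .taxdump_io import Taxonomy

__all__ = [
    "CandidateSet",
    "CandidateStore",
    "bounding_levels",
    "candidate_set",
    "apply_genus_species_rules",
]

_INF = float("inf")


@dataclass(frozen=True)
class CandidateSet:
    txid: int
    levels: frozenset[int]
    max_anc_level: int     # 0 when no ranked ancestor
    min_desc_level: int    # N + 1 when no ranked descendant


class CandidateStore:
    """Candidate sets over a taxonomy, kept current across assignments."""

    def __init__(self, taxonomy: Taxonomy, table: RankTable):
        self.t = taxonomy
        self.table = table
        self.n = table.n
        self.genus_level = table.level_of("Genus")
        self.species_level = table.level_of("Species")
        #: current level: original rank or assignment made during the run
        self.effective: dict[int, int | None] = {
            v: node.rank_level for v, node in taxonomy.nodes.items()
        }
        self.assigned: dict[int, int] = {}
        # min effective level within each node's subtree (inf if none)
        self._subtree_min: dict[int, float] = {}
        for v in reversed(taxonomy.depth_order()):
            m = _INF if self.effective[v] is None else float(self.effective[v])
            for c in taxonomy.children.get(v, ()):
                m = min(m, self._subtree_min[c])
            self._subtree_min[v] = m
        # "descendant with original Species rank" is a static property
        self._orig_species_below: dict[int, bool] = {}
        for v in reversed(taxonomy.depth_order()):
            flag = any(
                self._orig_species_below[c]
                or taxonomy.nodes[c].rank_level == self.species_level
                for c in taxonomy.children.get(v, ())
            )
            self._orig_species_below[v] = flag

    # -- state ---------------------------------------------------------

    def is_open(self, txid: int) -> bool:
        """Unranked and not yet assigned."""
        return self.effective[txid] is None

    def level(self, txid: int) -> int | None:
        return self.effective[txid]

    def assign(self, txid: int, level: int) -> None:
        if self.effective[txid] is not None:
            raise ValueError(f"txid {txid} already has level {self.effective[txid]}")
        self.effective[txid] = level
        self.assigned[txid] = level
        v: int | None = txid
        while v is not None:
            if self._subtree_min[v] <= level:
                break  # ancestors above are already at least this tight
            self._subtree_min[v] = float(level)
            v = None if v == self.t.root_txid else self.t.nodes[v].parent_txid

    # -- queries -------------------------------------------------------

    def bounding_levels(self, txid: int) -> tuple[int, int]:
        """(max ranked-ancestor level, min ranked-descendant level) under the
        current effective levels; 0 / N+1 when absent."""
        max_anc = 0
        for a in self.t.ancestors(txid):
            lvl = self.effective[a]
            if lvl is not None:
                max_anc = lvl  # nearest ranked ancestor has the max level
                break
        min_desc = min(
            (self._subtree_min[c] for c in self.t.children.get(txid, ())),
            default=_INF,
        )
        return max_anc, self.n + 1 if min_desc == _INF else int(min_desc)

    def _genus_species_allowed(self, txid: int) -> tuple[bool, bool]:
        node = self.t.nodes[txid]
        if node.is_unclassified or node.is_under_unclassified:
            return False, False
        species_ok = False
        if self.genus_level is not None:
            for a in self.t.ancestors(txid):
                if self.t.nodes[a].rank_level == self.genus_level:
                    species_ok = True
                    break
        genus_ok = self._orig_species_below[txid]
        return genus_ok, species_ok

    def candidate_set(self, txid: int) -> CandidateSet:
        if not self.is_open(txid):
            raise ValueError(f"txid {txid} is ranked; it has no candidate set")
        max_anc, min_desc = self.bounding_levels(txid)
        levels = set(range(max_anc + 1, min_desc))
        genus_ok, species_ok = self._genus_species_allowed(txid)
        if self.genus_level in levels and not genus_ok:
            levels.discard(self.genus_level)
        if self.species_level in levels and not species_ok:
            levels.discard(self.species_level)
        return CandidateSet(txid, frozenset(levels), max_anc, min_desc)


# -- stateless conveniences (pre-assignment view) ------------------------


def bounding_levels(t: Taxonomy, txid: int, table: RankTable) -> tuple[int, int]:
    """Bounding levels of an unranked node against the original ranks only."""
    if txid not in t.nodes:
        raise KeyError(f"unknown txid {txid}")
    return CandidateStore(t, table).bounding_levels(txid)


def candidate_set(t: Taxonomy, txid: int, table: RankTable) -> CandidateSet:
    """Candidate set of an unranked node against the original ranks only."""
    if txid not in t.nodes:
        raise KeyError(f"unknown txid {txid}")
    return CandidateStore(t, table).candidate_set(txid)


def apply_genus_species_rules(
    t: Taxonomy, txid: int, levels: set[int], table: RankTable
) -> set[int]:
    """Filter ``levels`` by the Species/Genus restrictions (original ranks)."""
    store = CandidateStore(t, table)
    genus_ok, species_ok = store._genus_species_allowed(txid)
    out = set(levels)
    if store.genus_level in out and not genus_ok:
        out.discard(store.genus_level)
    if store.species_level in out and not species_ok:
        out.discard(store.species_level)
    return out
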