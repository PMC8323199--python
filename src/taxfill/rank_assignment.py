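"""The rank-assignment engine.

Walking the tree breadth-first from the root, every unranked taxon with a
non-empty candidate set becomes the *node in analysis* (NA) and a cascade of
three rules decides its fate:

1. **Redundant levels.**  Count the consecutive levels below the NA whose
   nodes are all unranked with candidate sets equal to the NA's (a level
   containing a leaf ends the count after itself).  If the NA has fewer
   candidates than levels needing a rank (its own plus the redundant ones),
   the NA is left unranked so the deeper nodes can be ranked instead —
   favouring dichotomisation of the final tree.
2. **Coverable descendant.**  If some descendant reachable through an
   all-unranked path has no more candidates than the path has nodes
   (endpoints included), its candidates fit on the path; the NA takes the
   lowest level in its own candidate set, leaving the rest for the path.
3. **Priority rationing.**  Otherwise the subtree cannot absorb every
   candidate.  Take the longest downward path (LDP) of consecutive unranked
   taxa starting at the NA (ties: fewer distinct candidate levels along the
   path, then the lexicographically smallest txid sequence), sort the path's
   distinct candidate levels by rank priority, keep the first *n* (*n* =
   path length), and give the NA the lowest level among those kept.

After each assignment the candidate sets of the remaining unranked taxa are
updated, so later decisions see the tightened bounds.  Nodes under an
unclassified ancestor are never assigned.  Every decision is recorded in a
replayable log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .candidate_ranks import CandidateStore
from .rank_model import RankTable
from .taxdump_io import Taxonomy

__all__ = [
    "Assignment",
    "Decision",
    "assign_all",
    "redundant_level_count",
    "condition1_leave_unranked",
    "condition2_descendant_constraint",
    "find_ldp",
    "condition3_priority_pick",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Decision:
    """One visit of the engine: which rule fired and what it chose."""

    txid: int
    rule: str  # "skip-unclassified" | "empty" | "leave-1" | "lowest-2" | "priority-3"
    cr: int = 0
    rl: int = 0
    level: int | None = None


@dataclass
class Assignment:
    assigned: dict[int, int] = field(default_factory=dict)
    unassigned: set[int] = field(default_factory=set)
    log: list[Decision] = field(default_factory=list)


def redundant_level_count(t: Taxonomy, na_txid: int, store: CandidateStore) -> int:
    """Number of consecutive redundant levels below the NA.

    A level (within the NA's subtree) is redundant when every node on it is
    unranked/unassigned with the same candidate set as the NA, and the level
    above it is the NA's or a redundant level without leaf nodes.
    """
    na_cand = store.candidate_set(na_txid).levels
    rl = 0
    level = [na_txid]
    while True:
        nxt: list[int] = []
        for v in level:
            nxt.extend(t.children.get(v, ()))
        if not nxt:
            break
        if any(not store.is_open(v) for v in nxt):
            break
        if any(store.candidate_set(v).levels != na_cand for v in nxt):
            break
        rl += 1
        if any(not t.children.get(v) for v in nxt):
            break  # a leaf on a redundant level stops extension below it
        level = nxt
    return rl


def condition1_leave_unranked(cr: int, rl: int) -> bool:
    """True when the NA has fewer candidates than levels needing a rank."""
    return cr < 1 + rl


def condition2_descendant_constraint(
    t: Taxonomy, na_txid: int, store: CandidateStore
) -> bool:
    """Is there an unranked descendant whose candidate count is covered by
    the all-unranked path linking it to the NA (both endpoints counted)?"""
    frontier = [(na_txid, 1)]
    while frontier:
        v, path_len = frontier.pop()
        for c in t.children.get(v, ()):
            if not store.is_open(c):
                continue
            if len(store.candidate_set(c).levels) <= path_len + 1:
                return True
            frontier.append((c, path_len + 1))
    return False


def find_ldp(
    t: Taxonomy, na_txid: int, store: CandidateStore
) -> tuple[list[int], frozenset[int]]:
    """Longest downward path of consecutive unranked taxa from the NA.

    Among equally long paths prefer fewer distinct candidate levels, then the
    smallest txid sequence.  Returns the path and its distinct candidates.
    """
    best: tuple[int, int, tuple[int, ...], frozenset[int]] | None = None
    stack: list[tuple[list[int], frozenset[int]]] = [
        ([na_txid], store.candidate_set(na_txid).levels)
    ]
    while stack:
        path, cands = stack.pop()
        open_kids = [c for c in t.children.get(path[-1], ()) if store.is_open(c)]
        if not open_kids:
            key = (-len(path), len(cands), tuple(path), cands)
            if best is None or key[:3] < best[:3]:
                best = key
            continue
        for c in reversed(open_kids):
            stack.append((path + [c], cands | store.candidate_set(c).levels))
    assert best is not None
    return list(best[2]), best[3]


def condition3_priority_pick(
    ldp_len: int,
    ldp_candidates: frozenset[int],
    na_candidates: frozenset[int],
    table: RankTable,
) -> int | None:
    """Sort the LDP's candidate levels by priority, keep the first
    ``ldp_len``, and return the lowest kept level assignable to the NA
    (None when nothing kept fits the NA's own candidate set)."""
    if not ldp_candidates:
        return None
    by_priority = sorted(ldp_candidates, key=table.priority_of)
    extracted = by_priority[:ldp_len]
    usable = [lvl for lvl in extracted if lvl in na_candidates]
    return min(usable) if usable else None


def assign_all(
    t: Taxonomy,
    table: RankTable,
    include_unclassified: bool = False,
    store: CandidateStore | None = None,
) -> Assignment:
    """Run the cascade over every unranked taxon, root downwards (BFS,
    siblings in ascending-txid order).  Deterministic for fixed input."""
    if store is None:
        store = CandidateStore(t, table)
    result = Assignment()

    def record(d: Decision) -> None:
        result.log.append(d)
        if log.isEnabledFor(logging.DEBUG):
            log.debug(
                "NA %d: %s (CR=%d RL=%d level=%s)", d.txid, d.rule, d.cr, d.rl, d.level
            )

    for v in t.depth_order():
        if v == t.root_txid:
            continue  # the root is the level-0 anchor, never a rankable taxon
        node = t.nodes[v]
        if node.is_ranked:
            continue
        if node.is_under_unclassified and not include_unclassified:
            result.unassigned.add(v)
            record(Decision(v, "skip-unclassified"))
            continue
        cand = store.candidate_set(v)
        cr = len(cand.levels)
        if cr == 0:
            result.unassigned.add(v)
            record(Decision(v, "empty"))
            continue
        rl = redundant_level_count(t, v, store)
        if condition1_leave_unranked(cr, rl):
            result.unassigned.add(v)
            record(Decision(v, "leave-1", cr=cr, rl=rl))
            continue
        if condition2_descendant_constraint(t, v, store):
            level = min(cand.levels)
            store.assign(v, level)
            result.assigned[v] = level
            record(Decision(v, "lowest-2", cr=cr, rl=rl, level=level))
            continue
        ldp, ldp_cands = find_ldp(t, v, store)
        level = condition3_priority_pick(len(ldp), ldp_cands, cand.levels, table)
        if level is None:
            result.unassigned.add(v)
            record(Decision(v, "empty", cr=cr, rl=rl))
            continue
        store.assign(v, level)
        result.assigned[v] = level
        record(Decision(v, "priority-3", cr=cr, rl=rl, level=level))
    return result
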