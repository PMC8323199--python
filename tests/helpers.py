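"""Independent oracles and small utilities shared by the tests.

The candidate-set oracle below deliberately re-derives everything from first
principles — explicit enumeration of every ancestor and every descendant —
and shares no code with the implementation it cross-checks.
"""

from __future__ import annotations

from taxfill import RankTable, Taxonomy


def enumerate_ancestors(t: Taxonomy, txid: int) -> list[int]:
    out = []
    v = txid
    while v != t.root_txid:
        v = t.nodes[v].parent_txid
        out.append(v)
    return out


def enumerate_descendants(t: Taxonomy, txid: int) -> list[int]:
    out = []
    frontier = list(t.children.get(txid, ()))
    while frontier:
        v = frontier.pop()
        out.append(v)
        frontier.extend(t.children.get(v, ()))
    return out


def brute_force_candidate_set(
    t: Taxonomy,
    txid: int,
    table: RankTable,
    effective: dict[int, int | None] | None = None,
) -> set[int]:
    """Candidate levels of an unranked node by exhaustive enumeration.

    ``effective`` optionally supplies levels that include mid-run
    assignments; the Species/Genus preconditions always use original ranks.
    """
    if effective is None:
        effective = {v: t.nodes[v].rank_level for v in t.nodes}
    anc = enumerate_ancestors(t, txid)
    desc = enumerate_descendants(t, txid)
    anc_levels = [effective[a] for a in anc if effective[a] is not None]
    desc_levels = [effective[d] for d in desc if effective[d] is not None]
    lo = max(anc_levels, default=0)
    hi = min(desc_levels, default=table.n + 1)
    levels = set(range(lo + 1, hi))

    genus = table.level_of("Genus")
    species = table.level_of("Species")
    node = t.nodes[txid]
    unclassified = node.is_unclassified or node.is_under_unclassified
    has_genus_anc = any(t.nodes[a].rank_level == genus for a in anc)
    has_species_desc = any(t.nodes[d].rank_level == species for d in desc)
    if species in levels and (unclassified or not has_genus_anc):
        levels.discard(species)
    if genus in levels and (unclassified or not has_species_desc):
        levels.discard(genus)
    return levels


def leaf_level_multisets(ct) -> list[list[int]]:
    """Sorted level list along the root path of every completed-tree leaf."""
    return [
        sorted(ct.nodes[c].level for c in ct.path_to_root(leaf))
        for leaf in ct.leaves()
    ]
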