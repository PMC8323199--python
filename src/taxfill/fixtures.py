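"""Miniature taxdump fixtures.

Every generator returns a ``(nodes_text, names_text)`` pair in the taxdump
dialect, so the whole pipeline can be exercised without downloading NCBI
dumps.  The hand-built trees reproduce the canonical worked situations of
the rank-completion problem (node labels such as ``B_1`` or ``E_5`` follow
the conventional presentation of those examples); txids are small stable
integers cited by the tests, except where a well-known NCBI txid exists
(6072 Eumetazoa, 7711 Chordata, ...), which is then reused.

:func:`random_taxonomy` grows seeded random taxonomies with controllable
rank sparsity; generated trees always satisfy the input rank-hierarchy
invariant by construction, and identical seeds give byte-identical dumps.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .rank_model import RankTable, load_rank_table
from .taxdump_io import FIELD_SEP, RECORD_END, Taxonomy, parse_taxdump

__all__ = [
    "SyntheticTaxonomySpec",
    "fig1_tree",
    "fig2b_subtrees",
    "named_case_fixtures",
    "random_taxonomy",
    "FIXTURES",
    "load_fixture",
]

Row = tuple[int, int, str, str]  # txid, parent, rank name, scientific name


def _dump(rows: list[Row], common: dict[int, str] | None = None) -> tuple[str, str]:
    common = common or {}
    nodes_lines, names_lines = [], []
    for txid, parent, rank, name in sorted(rows):
        nodes_lines.append(f"{txid}{FIELD_SEP}{parent}{FIELD_SEP}{rank}{RECORD_END}")
        names_lines.append(
            f"{txid}{FIELD_SEP}{name}{FIELD_SEP}{FIELD_SEP}scientific name{RECORD_END}"
        )
        if txid in common:
            names_lines.append(
                f"{txid}{FIELD_SEP}{common[txid]}{FIELD_SEP}{FIELD_SEP}genbank common name{RECORD_END}"
            )
    return "\n".join(nodes_lines) + "\n", "\n".join(names_lines) + "\n"


def fig1_tree() -> tuple[str, str]:
    """Hypothetical tree for candidate-rank evaluation.

    Node B sits between a phylum (level 5) ancestor and a class (level 9)
    descendant, so it may assume subphylum, infraphylum or superclass
    ({6, 7, 8}).  Node M is squeezed between class (9) and subclass (10):
    its candidate set is empty.  Node K has a single candidate (10) and no
    unranked parent or child, the simple case that is assigned outright.
    """
    rows: list[Row] = [
        (1, 1, "no rank", "root"),
        (2, 1, "superkingdom", "SK"),
        (3, 2, "phylum", "A"),
        (4, 3, "no rank", "B"),
        (5, 4, "class", "C"),
        (6, 5, "no rank", "M"),
        (7, 6, "subclass", "D"),
        (8, 5, "no rank", "K"),
        (9, 8, "infraclass", "F"),
    ]
    return _dump(rows)


def fig2b_subtrees() -> dict[str, tuple[str, str]]:
    """Five small trees covering the decision cascade.

    * ``subtree1`` — redundant level: B_1 (one candidate) above C_1/D_1 with
      the same candidate set; B_1 is left unranked (and later deleted) so
      C_1 and D_1 can be ranked Kingdom.
    * ``subtree2``/``subtree3`` — coverable-descendant rule: the NA takes its
      lowest candidate; the covered node (C_2 / C_3) ends up unrankable and
      is deleted.
    * ``subtree4`` — coverable descendant where everything gets ranked.
    * ``subtree5`` — priority rationing on the chain B_5→C_5, followed by a
      type-2 interpolation (level-4 gap above the phylum leaf E_5) and the
      type-3 extension below E_5.
    """
    return {
        "subtree1": _dump([
            (1, 1, "no rank", "root"),
            (10, 1, "superkingdom", "A_1"),
            (11, 10, "no rank", "B_1"),
            (12, 11, "no rank", "C_1"),
            (13, 11, "no rank", "D_1"),
            (14, 12, "subkingdom", "E_1"),
            (15, 13, "subkingdom", "F_1"),
        ]),
        "subtree2": _dump([
            (1, 1, "no rank", "root"),
            (20, 1, "phylum", "A_2"),
            (21, 20, "no rank", "B_2"),
            (22, 21, "no rank", "C_2"),
            (23, 21, "infraphylum", "D_2"),
            (24, 22, "infraphylum", "E_2"),
        ]),
        "subtree3": _dump([
            (1, 1, "no rank", "root"),
            (30, 1, "class", "A_3"),
            (31, 30, "no rank", "B_3"),
            (32, 31, "no rank", "C_3"),
            (33, 31, "infraclass", "E_3"),
            (34, 32, "no rank", "D_3"),
            (35, 34, "cohort", "F_3"),
        ]),
        "subtree4": _dump([
            (1, 1, "no rank", "root"),
            (40, 1, "order", "A_4"),
            (41, 40, "no rank", "B_4"),
            (42, 41, "no rank", "C_4"),
            (43, 42, "parvorder", "D_4"),
        ]),
        "subtree5": _dump([
            (1, 1, "no rank", "root"),
            (50, 1, "superkingdom", "A_5"),
            (51, 50, "no rank", "B_5"),
            (52, 51, "no rank", "C_5"),
            (53, 52, "phylum", "E_5"),
        ]),
    }


def named_case_fixtures() -> dict[str, tuple[str, str]]:
    """The named corner cases.

    * ``rosodae`` — an unranked *classified* leaf under a Subfamily parent
      with no Genus ancestor and no Species descendant: the Species/Genus
      restrictions strike both ranks from its candidates and the priority
      rule hands it Tribe (level 22).
    * ``beringia`` — an unranked node named like a genus above a Species
      leaf, with no Genus in the lineage: Genus is retained (a Species
      descendant exists in the original data) and wins on priority.
    * ``nocardia`` — an unranked chain below an original Genus with no
      Species node: the upper node may (and does) take Species; the strain
      leaf keeps only below-Species candidates.
    * ``metazoa`` — a condensed excerpt of the animal subtree: Eumetazoa is
      assigned Subkingdom (level 3), Deuterostomia and Panarthropoda
      Superphylum (level 4); Bilateria is blocked by its superphylum
      descendant Scalidophora, Mandibulata and Pancrustacea by the subphylum
      Crustacea, and Vertebrata/Gnathostomata are redundant above
      Euteleostomi — all five are deleted.  Type-2 interpolation then mints
      spPhy_of_Cnidaria, sbPhy_of_Hexapoda and spCla_of_Chondrichthyes.
      (Chondrichthyes is attached directly under Craniata in this synthetic
      excerpt to keep the subtree small.)
    * ``crocodylia`` — archosaur/bird species used by the annotation
      examples: Crocodylia lacks Class and Superorder, Gallus gallus has
      both originally.
    """
    return {
        "rosodae": _dump([
            (1, 1, "no rank", "root"),
            (100, 1, "superkingdom", "Eukaryota"),
            (101, 100, "family", "Rosaceae"),
            (102, 101, "subfamily", "Rosoideae"),
            (103, 102, "no rank", "Rosodae"),
        ]),
        "beringia": _dump([
            (1, 1, "no rank", "root"),
            (110, 1, "superkingdom", "Eukaryota"),
            (111, 110, "family", "Brachybasidiaceae"),
            (112, 111, "no rank", "Beringia"),
            (113, 112, "species", "Beringia wynnei"),
        ]),
        "nocardia": _dump([
            (1, 1, "no rank", "root"),
            (120, 1, "superkingdom", "Bacteria"),
            (122, 120, "genus", "Nocardia"),
            (123, 122, "no rank", "Nocardia argentinensis"),
            (124, 123, "no rank", "Nocardia argentinensis ATCC 31306"),
        ]),
        "metazoa": _dump([
            (1, 1, "no rank", "root"),
            (2759, 1, "superkingdom", "Eukaryota"),
            (33208, 2759, "kingdom", "Metazoa"),
            (6072, 33208, "no rank", "Eumetazoa"),
            (6073, 6072, "phylum", "Cnidaria"),
            (33213, 6072, "no rank", "Bilateria"),
            (33511, 33213, "no rank", "Deuterostomia"),
            (7711, 33511, "phylum", "Chordata"),
            (89593, 7711, "subphylum", "Craniata"),
            (7742, 89593, "no rank", "Vertebrata"),
            (7776, 7742, "no rank", "Gnathostomata"),
            (117571, 7776, "no rank", "Euteleostomi"),
            (7898, 117571, "superclass", "Actinopterygii"),
            (8287, 117571, "superclass", "Sarcopterygii"),
            (40674, 8287, "class", "Mammalia"),
            (7777, 89593, "class", "Chondrichthyes"),
            (33317, 33213, "no rank", "Protostomia"),
            (1206794, 33317, "no rank", "Ecdysozoa"),
            (184837, 1206794, "superphylum", "Scalidophora"),
            (88770, 1206794, "no rank", "Panarthropoda"),
            (6656, 88770, "phylum", "Arthropoda"),
            (197563, 6656, "no rank", "Mandibulata"),
            (197562, 197563, "no rank", "Pancrustacea"),
            (6657, 197562, "subphylum", "Crustacea"),
            (6960, 197562, "superclass", "Hexapoda"),
            (50557, 6960, "class", "Insecta"),
        ]),
        "crocodylia": _dump(
            [
                (1, 1, "no rank", "root"),
                (2759, 1, "superkingdom", "Eukaryota"),
                (7711, 2759, "phylum", "Chordata"),
                (8782, 7711, "class", "Aves"),
                (8976, 8782, "superorder", "Galloanserae"),
                (9030, 8976, "genus", "Gallus"),
                (9031, 9030, "species", "Gallus gallus"),
                (1294634, 7711, "order", "Crocodylia"),
                (8495, 1294634, "genus", "Alligator"),
                (38654, 8495, "species", "Alligator sinensis"),
            ],
            common={9031: "chicken"},
        ),
    }


@dataclass(frozen=True)
class SyntheticTaxonomySpec:
    """Parameters of a random taxonomy.

    ``ranked_fraction`` is the probability that a node carries an original
    rank; ``rank_skip_bias`` the per-step probability of skipping a further
    level between a node and its nearest ranked ancestor (geometric);
    ``unclassified_fraction`` the probability that a node name carries an
    unclassified-entry marker.
    """

    seed: int
    n_leaves: int = 50
    max_depth: int = 8
    ranked_fraction: float = 0.5
    unclassified_fraction: float = 0.0
    rank_skip_bias: float = 0.3

    def validate(self, n_levels: int) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        for name in ("ranked_fraction", "unclassified_fraction", "rank_skip_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rank_skip_bias >= 1.0 and self.ranked_fraction > 0:
            raise ValueError("rank_skip_bias must be < 1 when ranks are drawn")


def random_taxonomy(
    spec: SyntheticTaxonomySpec, table: RankTable | None = None
) -> tuple[str, str, dict[str, int]]:
    """Seeded random taxonomy honoring the rank-hierarchy invariant.

    Returns (nodes_text, names_text, stats); stats report node/unranked
    counts.  Deterministic for a fixed spec.
    """
    if table is None:
        table = load_rank_table()
    spec.validate(table.n)
    rng = random.Random(spec.seed)
    n = table.n

    depth = {1: 0}
    anc_level = {1: 0}  # nearest ranked ancestor level, 0 at root
    rows: list[Row] = [(1, 1, "no rank", "root")]
    children: dict[int, int] = {1: 0}
    leaves = {1}
    next_txid = 2
    n_unranked = 0  # non-root unranked nodes

    while len(leaves) < spec.n_leaves or len(rows) < 2:
        eligible = [v for v in depth if depth[v] < spec.max_depth]
        parent = rng.choice(sorted(eligible))
        txid = next_txid
        next_txid += 1
        depth[txid] = depth[parent] + 1
        children[txid] = 0
        children[parent] += 1
        leaves.discard(parent)
        leaves.add(txid)

        level = None
        if anc_level[parent] < n and rng.random() < spec.ranked_fraction:
            level = anc_level[parent] + 1
            while level < n and rng.random() < spec.rank_skip_bias:
                level += 1
        anc_level[txid] = anc_level[parent] if level is None else level

        if level is None:
            n_unranked += 1
            rank_name = rng.choice(("no rank", "clade"))
        else:
            rank_name = table.by_level[level].name.lower()
        name = f"Taxon_{txid}"
        if rng.random() < spec.unclassified_fraction:
            name = f"{name} environmental samples"
        rows.append((txid, parent, rank_name, name))

    nodes_text, names_text = _dump(rows)
    stats = {
        "n_nodes": len(rows),
        "n_leaves": len(leaves),
        "n_unranked": n_unranked,
        "n_ranked": len(rows) - 1 - n_unranked,
    }
    return nodes_text, names_text, stats


def _all_named() -> dict[str, tuple[str, str]]:
    out = {"fig1": fig1_tree()}
    out.update({f"fig2b_{k}": v for k, v in fig2b_subtrees().items()})
    out.update(named_case_fixtures())
    return out


#: name -> (nodes_text, names_text) for every hand-built fixture
FIXTURES = _all_named


def load_fixture(name: str, table: RankTable | None = None) -> Taxonomy:
    """Parse a named fixture straight into a Taxonomy."""
    if table is None:
        table = load_rank_table()
    fixtures = _all_named()
    if name not in fixtures:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(fixtures)}")
    nodes_text, names_text = fixtures[name]
    return parse_taxdump(nodes_text, names_text, table)
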