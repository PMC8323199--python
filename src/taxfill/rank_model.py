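"""The catalogue of taxonomic ranks.

NCBI Taxonomy currently uses 41 named ranks, from Superkingdom down to
Isolate.  Every rank carries

* a **level** (1 = Superkingdom ... 41 = Isolate) giving its position in the
  rank hierarchy: along any lineage, levels must strictly increase from root
  to tip;
* an **abbreviation** used verbatim as the prefix of names minted for nodes
  that the completion algorithm ranks or creates (``sbCla_Theria``,
  ``Tri_of_Homo``, ...);
* a **priority** (1 = best) used when an unranked node could legally take
  several ranks: ranks that appear in many leaf lineages are handed out
  first.  Priorities are the ranks ordered by decreasing leaf-lineage
  frequency, ties broken by the smaller (higher) level.

The default table below reproduces the NCBI rank census of late 2020
(``DEFAULT_LINEAGE_COUNTS`` holds the number of leaf lineages containing each
rank); :func:`priorities_from_frequencies` recomputes the priority column
from those counts, and the shipped values are exactly that recomputation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

__all__ = [
    "Rank",
    "RankTable",
    "load_rank_table",
    "write_rank_table",
    "priorities_from_frequencies",
    "abbreviation_for",
    "DEFAULT_RANK_ROWS",
    "DEFAULT_LINEAGE_COUNTS",
]


@dataclass(frozen=True)
class Rank:
    """One taxonomic rank: its level, name, name abbreviation and priority."""

    level: int
    name: str
    abbreviation: str
    priority: int


#: (level, name, abbreviation, priority) for the 41 NCBI ranks.
DEFAULT_RANK_ROWS: tuple[tuple[int, str, str, int], ...] = (
    (1, "Superkingdom", "spKin", 1),
    (2, "Kingdom", "Kin", 8),
    (3, "Subkingdom", "sbKin", 21),
    (4, "Superphylum", "spPhy", 38),
    (5, "Phylum", "Phy", 6),
    (6, "Subphylum", "sbPhy", 9),
    (7, "Infraphylum", "inPhy", 40),
    (8, "Superclass", "spCla", 20),
    (9, "Class", "Cla", 7),
    (10, "Subclass", "sbCla", 10),
    (11, "Infraclass", "inCla", 14),
    (12, "Cohort", "Coh", 16),
    (13, "Subcohort", "sbCoh", 29),
    (14, "Superorder", "spOrd", 19),
    (15, "Order", "Ord", 5),
    (16, "Suborder", "sbOrd", 12),
    (17, "Infraorder", "inOrd", 17),
    (18, "Parvorder", "prOrd", 23),
    (19, "Superfamily", "spFam", 13),
    (20, "Family", "Fam", 4),
    (21, "Subfamily", "sbFam", 11),
    (22, "Tribe", "Tri", 15),
    (23, "Subtribe", "sbTri", 24),
    (24, "Genus", "Gen", 2),
    (25, "Subgenus", "sbGen", 26),
    (26, "Section", "Sec", 30),
    (27, "Subsection", "sbSec", 36),
    (28, "Series", "Ser", 37),
    (29, "Subseries", "sbSer", 41),
    (30, "Species group", "Sgr", 27),
    (31, "Species subgroup", "sbSgr", 31),
    (32, "Species", "Spe", 3),
    (33, "Forma specialis", "Fsp", 32),
    (34, "Subspecies", "sbSpe", 25),
    (35, "Varietas", "Var", 28),
    (36, "Subvariety", "sbVar", 39),
    (37, "Forma", "For", 34),
    (38, "Serogroup", "Srg", 35),
    (39, "Serotype", "Srt", 18),
    (40, "Strain", "Str", 22),
    (41, "Isolate", "Iso", 33),
)

#: Number of leaf lineages containing each rank (NCBI census, late 2020).
#: ``priorities_from_frequencies`` on this map reproduces the default
#: priority column above.
DEFAULT_LINEAGE_COUNTS: dict[int, int] = {
    1: 728071, 2: 648200, 3: 46229, 4: 70, 5: 722901, 6: 573559, 7: 0,
    8: 73676, 9: 715953, 10: 306936, 11: 177636, 12: 155939, 13: 8220,
    14: 101075, 15: 723930, 16: 220298, 17: 140252, 18: 43046, 19: 191499,
    20: 726481, 21: 270677, 22: 158026, 23: 34578, 24: 726932, 25: 18815,
    26: 5302, 27: 131, 28: 74, 29: 0, 30: 11709, 31: 964, 32: 726733,
    33: 829, 34: 29339, 35: 8359, 36: 5, 37: 521, 38: 356, 39: 107446,
    40: 43064, 41: 641,
}


class RankTableError(ValueError):
    """Raised when a rank configuration violates the table invariants."""


class RankTable:
    """Ordered, validated catalogue of ranks with lookup maps.

    Levels must be contiguous from 1 to N; abbreviations and names unique;
    priorities a permutation of 1..N.  Name lookup is case-insensitive so
    that NCBI's lowercase rank strings ("superkingdom", "species group", ...)
    resolve against the capitalised display names.
    """

    def __init__(self, ranks: Iterable[Rank]):
        ranks = tuple(sorted(ranks, key=lambda r: r.level))
        if not ranks:
            raise RankTableError("rank table is empty")
        levels = [r.level for r in ranks]
        if levels != list(range(1, len(ranks) + 1)):
            raise RankTableError(
                f"levels not contiguous from 1: got {levels}"
            )
        self.ranks = ranks
        self.by_level: dict[int, Rank] = {r.level: r for r in ranks}
        self.by_name: dict[str, Rank] = {}
        self.by_abbreviation: dict[str, Rank] = {}
        for r in ranks:
            key = r.name.casefold()
            if key in self.by_name:
                raise RankTableError(f"duplicate rank name: {r.name!r}")
            if not r.abbreviation or any(c.isspace() for c in r.abbreviation):
                raise RankTableError(
                    f"bad abbreviation {r.abbreviation!r} for level {r.level}"
                )
            if r.abbreviation in self.by_abbreviation:
                raise RankTableError(
                    f"duplicate abbreviation: {r.abbreviation!r}"
                )
            self.by_name[key] = r
            self.by_abbreviation[r.abbreviation] = r
        prios = sorted(r.priority for r in ranks)
        if prios != list(range(1, len(ranks) + 1)):
            raise RankTableError(
                f"priorities are not a permutation of 1..{len(ranks)}"
            )

    @property
    def n(self) -> int:
        """Number of ranks (the depth of every completed lineage)."""
        return len(self.ranks)

    def level_of(self, rank_name: str) -> int | None:
        """Level for an NCBI rank string, or None if not in the table."""
        r = self.by_name.get(rank_name.casefold())
        return None if r is None else r.level

    def priority_of(self, level: int) -> int:
        return self.by_level[level].priority

    def __len__(self) -> int:
        return len(self.ranks)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RankTable) and self.ranks == other.ranks

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RankTable({len(self.ranks)} ranks)"


_HEADER = ("level", "name", "abbreviation", "priority")


def load_rank_table(config: str | Path | IO[str] | None = None) -> RankTable:
    """Load the rank catalogue.

    Without ``config`` the default 41-rank NCBI table is returned.  ``config``
    may be a path to, or an open handle / string of, a tab-separated file with
    the header ``level name abbreviation priority``.
    """
    if config is None:
        return RankTable(Rank(*row) for row in DEFAULT_RANK_ROWS)
    if isinstance(config, Path):
        text = config.read_text()
    elif isinstance(config, str):
        p = Path(config)
        text = p.read_text() if p.exists() else config
    else:
        text = config.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise RankTableError("empty rank config")
    header = tuple(h.strip().lower() for h in lines[0].split("\t"))
    if header[: len(_HEADER)] != _HEADER:
        raise RankTableError(
            f"rank config header must start with {_HEADER}, got {header}"
        )
    ranks = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) < 4:
            raise RankTableError(f"rank config line {i}: expected 4 columns")
        try:
            ranks.append(
                Rank(int(parts[0]), parts[1], parts[2], int(parts[3]))
            )
        except ValueError as e:
            raise RankTableError(f"rank config line {i}: {e}") from None
    return RankTable(ranks)


def write_rank_table(table: RankTable, dest: str | Path | IO[str] | None = None) -> str:
    """Serialize a table to the tab-separated config format (also the
    ``rank`` output table).  Returns the text; writes it if ``dest`` given."""
    buf = io.StringIO()
    buf.write("\t".join(_HEADER) + "\n")
    for r in table.ranks:
        buf.write(f"{r.level}\t{r.name}\t{r.abbreviation}\t{r.priority}\n")
    text = buf.getvalue()
    if dest is not None:
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(text)
        else:
            dest.write(text)
    return text


def priorities_from_frequencies(
    rank_lineage_counts: Mapping[int, int], n: int | None = None
) -> dict[int, int]:
    """Priority per level from leaf-lineage frequencies.

    The most frequent rank gets priority 1.  Ties go to the smaller level
    (the higher rank), which keeps the ordering deterministic.  Every level
    1..n must be present in the count map.
    """
    if n is None:
        n = max(rank_lineage_counts, default=0)
    missing = [lvl for lvl in range(1, n + 1) if lvl not in rank_lineage_counts]
    if missing:
        raise ValueError(f"missing lineage counts for levels {missing}")
    for lvl, c in rank_lineage_counts.items():
        if c < 0:
            raise ValueError(f"negative count for level {lvl}")
    order = sorted(range(1, n + 1), key=lambda lvl: (-rank_lineage_counts[lvl], lvl))
    return {lvl: i + 1 for i, lvl in enumerate(order)}


def abbreviation_for(level: int, table: RankTable) -> str:
    """The name prefix for ``level`` (e.g. 9 -> "Cla")."""
    if level not in table.by_level:
        raise KeyError(f"rank level {level} out of range 1..{table.n}")
    return table.by_level[level].abbreviation
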