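"""Output tables and the annotation convenience.

Seven tables are produced from a completed tree:

======================  =====================================================
``lin``                 per-txid row of N identifier codes, one per rank
``lin_name``            the same rows with display names instead of codes
``tree_complete``       parent/child code pairs of the completed tree
``tree_all``            parent/child pairs over *all* original taxa — the
                        NCBI topology with unassigned unranked taxa kept
                        (bare ``<txid>.000`` codes, flagged in ``status``)
``tree_original``       the NCBI parent/child txid pairs verbatim
``tax_data``            per-code name, common name, rank level, node type
``rank``                the rank catalogue (level/name/abbreviation/priority)
======================  =====================================================

TSV is the canonical format; SQL emission is a thin serializer of the same
frames with codes quoted as strings (a code like ``6072.031`` must never
round-trip through a float).  Row order is deterministic, so emitting twice
yields byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .rank_model import RankTable
from .taxdump_io import Taxonomy
from .tree_completion import CompletedTree, PrunedTree, lineage_row

__all__ = ["TableSet", "build_tables", "emit_tables", "annotate", "NOT_FOUND"]

NOT_FOUND = "NOT FOUND"

TABLE_NAMES = (
    "lin",
    "lin_name",
    "tree_complete",
    "tree_all",
    "tree_original",
    "tax_data",
    "rank",
)


@dataclass
class TableSet:
    lin: pd.DataFrame
    lin_name: pd.DataFrame
    tree_complete: pd.DataFrame
    tree_all: pd.DataFrame
    tree_original: pd.DataFrame
    tax_data: pd.DataFrame
    rank: pd.DataFrame
    rank_table: RankTable

    def __iter__(self):
        for name in TABLE_NAMES:
            yield name, getattr(self, name)


def build_tables(
    ct: CompletedTree,
    pruned: PrunedTree,
    table: RankTable,
    separator: str = "_",
    display: bool = False,
) -> TableSet:
    """Materialize all seven tables for every txid of the input taxonomy."""
    t = pruned.taxonomy
    rank_cols = [r.name for r in table.ranks]
    lin_rows, name_rows = [], []
    extra_tax_data: dict[str, tuple[str, int, int, int]] = {}
    for txid in sorted(t.nodes):
        row = lineage_row(ct, t, txid, table, separator, display)
        lin_rows.append((txid, *row.codes))
        name_rows.append((txid, *row.names))
        # virtual type-3 entries synthesized for internal taxa must still
        # resolve in tax_data
        for code, name, lvl in zip(row.codes, row.names, range(1, table.n + 1)):
            if code not in ct.nodes and code not in extra_tax_data:
                extra_tax_data[code] = (name, lvl, 3, int(code.split(".")[0]))

    lin = pd.DataFrame(lin_rows, columns=["txid", *rank_cols])
    lin_name = pd.DataFrame(name_rows, columns=["txid", *rank_cols])

    tree_complete = pd.DataFrame(
        ct.edges(), columns=["parent_code", "child_code"]
    ).sort_values(["parent_code", "child_code"], kind="mergesort", ignore_index=True)

    all_rows = []
    for txid in sorted(t.nodes):
        if txid == t.root_txid:
            continue
        node = t.nodes[txid]
        code = ct.code_of_txid.get(txid, f"{txid}.000")
        parent_code = ct.code_of_txid.get(node.parent_txid, f"{node.parent_txid}.000")
        if txid in pruned.assignment.assigned:
            status = "assigned"
        elif node.rank_level is not None:
            status = "original"
        else:
            status = "unassigned"
        all_rows.append((parent_code, code, status))
    tree_all = pd.DataFrame(
        all_rows, columns=["parent_code", "child_code", "status"]
    )

    tree_original = pd.DataFrame(
        [
            (t.nodes[txid].parent_txid, txid)
            for txid in sorted(t.nodes)
            if txid != t.root_txid
        ],
        columns=["parent_txid", "txid"],
    )

    tax_rows = []
    for code in sorted(ct.nodes):
        node = ct.nodes[code]
        common = (
            t.nodes[node.source_txid].common_name or ""
            if node.node_type in (0, 1)
            else ""
        )
        tax_rows.append(
            (code, node.display_name, common, node.level, node.node_type,
             node.source_txid)
        )
    for code, (name, lvl, ntype, src) in extra_tax_data.items():
        tax_rows.append((code, name, "", lvl, ntype, src))
    tax_data = (
        pd.DataFrame(
            tax_rows,
            columns=[
                "code",
                "scientific_name",
                "common_name",
                "level",
                "node_type",
                "source_txid",
            ],
        )
        .sort_values("code", kind="mergesort", ignore_index=True)
    )

    rank = pd.DataFrame(
        [(r.level, r.name, r.abbreviation, r.priority) for r in table.ranks],
        columns=["level", "name", "abbreviation", "priority"],
    )
    return TableSet(
        lin, lin_name, tree_complete, tree_all, tree_original, tax_data, rank, table
    )


def emit_tables(
    tables: TableSet, destination: str | Path, format: str = "tsv"
) -> list[Path]:
    """Write the seven tables under ``destination``; returns the paths."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in tables:
        if format == "tsv":
            path = dest / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
        elif format == "sql":
            path = dest / f"{name}.sql"
            path.write_text(_sql_dump(name, frame))
        else:
            raise ValueError(f"unknown format {format!r} (use 'tsv' or 'sql')")
        paths.append(path)
    return paths


def _sql_dump(name: str, frame: pd.DataFrame) -> str:
    def sql_type(dtype) -> str:
        return "INTEGER" if pd.api.types.is_integer_dtype(dtype) else "TEXT"

    cols = ", ".join(
        f"`{c}` {sql_type(frame[c].dtype)}" for c in frame.columns
    )
    out = [f"DROP TABLE IF EXISTS `{name}`;", f"CREATE TABLE `{name}` ({cols});"]
    for row in frame.itertuples(index=False):
        vals = ", ".join(
            str(v) if isinstance(v, (int, float)) and not isinstance(v, bool)
            else "'" + str(v).replace("'", "''") + "'"
            for v in row
        )
        out.append(f"INSERT INTO `{name}` VALUES ({vals});")
    return "\n".join(out) + "\n"


def annotate(
    txids: Iterable[int], ranks: Sequence[str], tables: TableSet
) -> pd.DataFrame:
    """Per-txid names at the requested ranks (e.g. Class, Superorder).

    Unknown txids yield explicit NOT FOUND markers rather than dropped rows —
    downstream profile pipelines depend on stable row counts.
    """
    for r in ranks:
        if r.casefold() not in tables.rank_table.by_name:
            raise KeyError(f"unknown rank name {r!r}")
    canonical = [tables.rank_table.by_name[r.casefold()].name for r in ranks]
    lookup = tables.lin_name.set_index("txid")
    rows = []
    for txid in txids:
        if txid in lookup.index:
            rows.append((txid, *(lookup.at[txid, c] for c in canonical)))
        else:
            rows.append((txid, *([NOT_FOUND] * len(canonical))))
    return pd.DataFrame(rows, columns=["txid", *canonical])
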