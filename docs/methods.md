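# Methods

## Model

The input is a rooted tree whose nodes (taxa) carry a numeric identifier
(txid), a scientific name, and optionally one of N taxonomic ranks.  Ranks
are totally ordered by *level* (1 = Superkingdom … N = Isolate; N = 41 by
default) and must strictly increase along any root-to-tip path.  The output
is a tree over the same taxa plus created nodes in which every root-to-leaf
path visits each level exactly once; the original root sits above level 1
as a level-0 anchor and is never ranked or deleted.

Three operations produce the completed tree:

1. *rank assignment* gives at most one rank to each existing unranked
   ("no rank"/"clade") taxon (type-1 nodes);
2. *interpolation* creates nodes for levels no existing taxon can carry
   (type-2 nodes, one chain per skipping edge, all named after the ranked
   child end of the edge);
3. *leaf extension* appends chains below leaves up to level N (type-3).

Unassigned unranked taxa are deleted from the completed tree, but the
package retains the original topology: the `tree_all` table keeps them
(flagged) so the NCBI edge set is reproduced exactly, and `tree_original`
stores the parsed edges verbatim.

## Candidate sets and the assignment cascade

An unranked node may assume exactly the levels strictly between the lowest
rank among its ancestors and the highest rank among **all** its descendants
(not only children — a deep ranked descendant blocks just as well).  Two
rank-specific restrictions apply, both evaluated against *original* ranks
only (ranks assigned during the run never satisfy them): Species requires
an original-Genus ancestor; Genus requires an original-Species descendant;
neither is given to a node that is (or sits below) an unclassified entry.
The unclassified-name term list (unpublished, unidentified, unassigned,
environmental sample(s), incertae sedis) is extended with "unclassified"
itself; the extension can be disabled (`extra_terms=False` /
`--include-unclassified` affects subtree assignment separately).

The engine visits unranked taxa breadth-first from the root, siblings in
ascending-txid order (the traversal the level-by-level narrative of the
cascade implies, and one that fixes determinism).  For each NA with a
non-empty candidate set:

* **Condition 1** counts redundant levels (RL) below the NA: a level is
  redundant when *all* its nodes are unranked with candidate sets equal to
  the NA's, and the level above is the NA's or a redundant level without
  leaves.  A redundant level containing a leaf is counted but stops the
  extension below it (one of two defensible readings; documented here as
  the package's choice).  If `CR < 1 + RL` the NA stays unranked.
* **Condition 2** searches the subtree through all-unranked paths for a
  descendant whose candidate count is ≤ the node count of the path,
  endpoints included.  The inclusive count is what makes the textbook
  two-node chain behave as published (the upper node ranked with its lowest
  candidate, the covered node later deleted).  The NA then takes
  `min(candidates)`.
* **Condition 3** extracts, from the distinct candidates along the longest
  downward unranked path (ties: fewer distinct candidates, then smaller
  txid sequence), the best-priority `n = |path|` levels and assigns the NA
  the lowest extracted level.  If no extracted level lies in the NA's own
  candidate set (possible when deep path members contribute levels below
  the NA's range), the NA is left unranked — a degenerate case no fixture
  triggers, handled for totality.

Candidate sets are maintained incrementally: assignments only add ranked
levels, so each subtree's cached minimum level is updated by a single walk
to the root, and ancestor bounds are read by a walk up (O(depth) per
query).  Tests cross-check against a brute-force enumeration oracle.

## Priorities

Priorities order the ranks by the number of leaf lineages containing them
(most frequent = priority 1), ties broken toward the smaller level — a
deterministic rule that favours the conventional main ranks.  The shipped
default priority column equals `priorities_from_frequencies` applied to the
bundled leaf-lineage census (late-2020 NCBI numbers); a test pins this
equality.  Custom rank tables (any N) are accepted as TSV configs with
validated invariants (contiguous levels, unique abbreviations, permutation
priorities).

A consequence worth noting: with the current census, Serotype (priority 18)
outranks Subspecies (priority 25), so a strain-like unranked leaf directly
below a freshly assigned Species receives Serotype.  Accounts of earlier
data (before the serotype/strain/isolate ranks were populated) report
Subspecies for the same configuration; the difference is purely the
priority census, not the cascade.

## Naming, codes, tables

Created/modified names are `<abbrev><sep><name>` (type 1),
`<abbrev><sep>of<sep><name>` (type 2, named after the ranked child end of
the gap edge — naming after the *lower*-rank end would wrongly merge
sibling lineages into one created taxon), and `<abbrev><sep>in<sep><name>`
(type 3, named after the leaf).  The separator defaults to `_`
(`sbCla_Theria`); `display=True` uses spaces.  Codes are
`<txid>.<LL><T>` strings (two-digit level, one-digit type; `000` for
originally ranked taxa) and are emitted quoted in SQL — parsing them as
decimals would destroy suffixes like `.031`.

Lineage rows (`lin`, `lin_name`) contain one entry per level for every
input txid.  For an internal taxon at level k, columns k+1…N are filled
with *virtual* type-3 entries coded from that txid; they are row-level
constructs, not tree nodes (for leaves they coincide with the real type-3
chain), but each is registered in `tax_data` so every code in `lin`
resolves.  Deleted unranked taxa resolve to their nearest retained
ancestor's row (switchable via `resolve_deleted`).

## Synthetic data

The fixture module provides (a) hand-built miniature taxdumps reproducing
the canonical worked situations — the candidate-set example, the five
decision-cascade subtrees, the Species/Genus corner cases and a condensed
Metazoa excerpt (its Chondrichthyes branch is attached one level higher
than in the real tree to keep the excerpt small while still producing all
the published outcomes) — and (b) a seeded random generator.

The generator grows a tree to a requested leaf count by random attachment
under a depth cap, draws each node's rankedness with probability
`ranked_fraction` (default 0.5 — roughly the mix of ranked and unranked
taxa in sparse regions of real taxonomies), skips levels geometrically
with `rank_skip_bias` (default 0.3), and salts names with unclassified
markers at `unclassified_fraction` (default 0; tests use 0.05, the order of
magnitude of unclassified taxa in real dumps).  Trees satisfy the input
rank-hierarchy invariant by construction and serialize byte-reproducibly
for a fixed seed.  What the generator does **not** emulate: real name
vocabularies, the extreme size skew of NCBI clades, merged/deleted-node
files, and rank vocabularies outside the configured table — so green tests
demonstrate algorithmic correctness on taxdump-shaped input, not
robustness to every quirk of a production dump.

Test and acceptance runs use taxonomies of ≤ 2,000 nodes (hundreds of
leaves), a size at which the whole pipeline runs in well under a second
while still exercising every rule; the full NCBI dump (~10⁷ nodes) is out
of scope for the bundled checks.

## Numerical / degenerate choices

* Children lists are sorted ascending by txid everywhere; all emitted
  tables are sorted, so repeated builds are byte-identical.
* Nodes with empty candidate sets are skipped (later deleted), as are
  nodes under unclassified ancestors (which still receive type-2/3
  completion so every txid yields a full row).
* Input with a ranked descendant at a level ≤ a ranked ancestor is
  rejected at parse time rather than repaired.
* A single-node taxonomy (root only) completes to one type-3 chain below
  the level-0 root.

## Known limitations

* The cascade is greedy, as specified; it does not globally maximise the
  number of ranked taxa.
* Rank synonymy (e.g. "domain" for "superkingdom") is not resolved beyond
  the configured table.
* merged.dmp / delnodes.dmp are ignored; txids from superseded dumps will
  not resolve.
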