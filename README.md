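# taxfill

Complete NCBI-style taxonomies so that **every lineage carries exactly one
node per taxonomic rank**.

## The problem

NCBI Taxonomy organises every sequenced organism in a single rooted tree,
but its rank annotation is sparse and inconsistent: many lineages lack a
Class or an Order, and the tree is full of named, rank-less "no rank" /
"clade" nodes.  Any analysis that groups data *by rank* — metagenomic
profiles, per-class BLAST summaries, rank-coloured phylogenies — then
collapses all the missing entries into an uninformative NULL bucket.

`taxfill` transforms a taxdump-format taxonomy into a hierarchically
complete tree over the 41 NCBI ranks (Superkingdom = level 1 … Isolate =
level 41), in which every root-to-leaf path visits levels 1…41 exactly
once, while keeping the original parent/child relations fully recoverable.

## The algorithm

Each unranked node has a **candidate set** — the rank levels *L* with
`max(ranked ancestor levels) < L < min(ranked descendant levels)`, so the
hierarchy (levels strictly increase toward the tips) is never violated.
Species and Genus are further restricted: Species requires an original
Genus ancestor, Genus an original Species descendant, and neither may go to
an unclassified entry (*environmental samples*, *incertae sedis*, …).

Walking breadth-first from the root, each unranked node in analysis (NA)
passes through a cascade:

1. **Redundant levels** — if the levels directly below the NA consist of
   unranked nodes with the *same* candidate set, and the NA has fewer
   candidates than levels needing a rank (`CR < 1 + RL`), the NA is left
   unranked so the deeper nodes can be ranked instead.
2. **Coverable descendant** — if some descendant along an all-unranked path
   has no more candidates than the path has nodes, the NA takes the lowest
   level in its candidate set.
3. **Priority rationing** — otherwise, take the longest downward path of
   consecutive unranked taxa from the NA, sort its candidate levels by rank
   *priority* (ranks frequent in leaf lineages first: Superkingdom, Genus,
   Species, Family, …), keep the first *n* (*n* = path length), and give
   the NA the lowest kept level.

The tree is then restructured: unassigned unranked nodes are deleted
(children re-attach to the nearest kept ancestor), level gaps are filled
with interpolated nodes, and leaves above level 41 grow appended chains.
Created/modified nodes are named and coded so they can never be mistaken
for real taxa:

| type | meaning              | name                  | code          |
|------|----------------------|-----------------------|---------------|
| 0    | originally ranked    | unchanged             | `9606.000`    |
| 1    | unranked, rank given | `sbCla_Theria`        | `6072.031`    |
| 2    | interpolated         | `Tri_of_Homo`         | `<txid>.222`  |
| 3    | appended below leaf  | `sbSpe_in_Sus scrofa` | `<txid>.343`  |

(code = txid, a dot, two digits of rank level, one digit of node type).

## Worked example

The bundled `metazoa` fixture is a condensed animal subtree with the
classic trouble spots (rank-less Eumetazoa/Bilateria, a Superclass-less
Insecta lineage, …):

```sh
taxfill fixtures metazoa --out fxdemo
taxfill lineage --taxdump fxdemo 50557 | cut -f1-10
```

prints the first columns of the completed Insecta lineage:

```
50557  Eukaryota  Metazoa  sbKin_Eumetazoa  spPhy_Panarthropoda  Arthropoda  sbPhy_of_Hexapoda  inPhy_of_Hexapoda  Hexapoda  Insecta
```

Reading it: the "no rank" taxa Eumetazoa and Panarthropoda were borrowed as
Subkingdom and Superphylum (type 1, e.g. code `6072.031`); no existing node
could take Subphylum — Mandibulata and Pancrustacea are blocked by their
subphylum descendant Crustacea — so `sbPhy_of_Hexapoda` (type 2) was
interpolated above the first ranked descendant Hexapoda.  Bilateria,
blocked by the superphylum Scalidophora, was deleted; the original edges
nevertheless remain available in the `tree_all` output.

```sh
taxfill build --taxdump fxdemo --out out   # writes the 7 tables
```

produces `lin` / `lin_name` (one row per txid, 41 rank columns),
`tree_complete`, `tree_all`, `tree_original`, `tax_data` and `rank` as TSV
(`--format sql` for SQL dumps).  Internal taxa get their lower columns
filled with below-leaf entries, so every row is complete, e.g. the Phylum
column of the superkingdom Eukaryota reads `Phy_in_Eukaryota`.

Annotation of txid lists at chosen ranks (the building block for
metagenomic profiles and rank-coloured trees):

```sh
taxfill annotate --taxdump fxdemo --txids ids.txt --rank-names Class,Superorder
```

Unknown txids are reported as `NOT FOUND` rather than silently dropped.

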