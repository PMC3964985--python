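# phylomekit

Analysis machinery for **phylomes** — complete collections of gene
phylogenies, one tree per seed gene of a genome. Given gene trees whose
leaves encode a sequence identifier plus a species mnemonic (e.g.
`Phy00086SJ_HUMAN`) and a rooted reference species tree, phylomekit:

- roots each gene tree relative to its seed gene,
- labels every internal node **duplication** or **speciation** by
  *species overlap*,
- derives typed orthology and paralogy calls, optionally restricted by the
  *close2seed* filter, and scores them for consistency across a tree
  collection,
- dates nodes phylostratigraphically against a taxonomy,
- reconciles gene trees with species trees (duplication/loss counting and
  exhaustive gene-tree-parsimony search),
- compares tree versions and orthology sets (normalized Robinson–Foulds,
  pair conservation), and
- filters alignment columns by residue-pair consistency across alternative
  alignments (the heads-or-tails idea).

A built-in duplication–loss simulator generates species trees, gene trees
and ground-truth event logs, so every claim the package makes can be tested
without external data.

It is aimed at people doing comparative genomics who need the *analytical*
steps of a phylome pipeline — not homology search, alignment or ML tree
inference, which upstream tools already do well.

## The core rules

**Species overlap.** For an internal node with children subtending species
sets `A` and `B`, the overlap score is the Jaccard index

```
sos = |A ∩ B| / |A ∪ B|
```

(multifurcations take the maximum over child pairs). The node is a
duplication iff `sos > t`; the default threshold `t = 0` means any shared
species implies a duplication. Unlike strict reconciliation, this needs no
trust in the species tree beyond the leaf set.

**Orthology.** Two genes are orthologs iff the event at their last common
ancestor is a speciation (same-species pairs are always paralogs). Calls
are typed by counting co-orthologs in the two child clades of that node:
(1,1) → one-to-one, (1,n) → one-to-many, (m,n) → many-to-many.

**close2seed.** Keep only pairs in which at least one member is among the
`k` leaves nodally closest to the seed (default `k = 30`); distant parts of
large trees carry less reliable signal for pairwise calls.

**Consistency.** For a pair of genes co-occurring in `n` trees of a
collection, the consistency score is the fraction of those trees in which
the pair is orthologous.

**Reconciliation.** Each gene-tree node maps to the LCA (in the species
tree) of its descendant species; a node is a duplication iff its mapping
equals a child's mapping. Losses on an edge with species-tree distance `d`
count `d − 1` below a speciation and `d` below a duplication. Gene-tree
parsimony sums this cost over a tree collection; for ≤ 8 species all rooted
binary species topologies are searched exhaustively.

**Column filtering.** A residue pair is supported by an alternative
alignment if that alignment also places the two residues in one column.
Strict mode drops any consensus column containing a pair observed in at
most one underlying alignment; fraction mode thresholds the mean pair
support.

## Worked example

A five-gene family seeded on `Phy001_HUMAN`, with a second HUMAN copy:

```bash
$ cat tree.nwk
(((Phy001_HUMAN:0.08,Phy002_PANTR:0.09):0.20,(Phy003_HUMAN:0.07,Phy004_MOUSE:0.30):0.18):0.45,Phy005_YEAST:0.90);
$ cat species.nwk
(((HUMAN,PANTR)Primates,MOUSE)Mammalia,YEAST)Eukaryota;

$ phylomekit label --tree tree.nwk --species-tree species.nwk \
      --seed Phy001_HUMAN --out labeled.nhx
$ cat labeled.nhx
(Phy005_YEAST:0.675[&&NHX:age=3:S=YEAST],((Phy003_HUMAN:0.07[&&NHX:age=0:S=HUMAN],Phy004_MOUSE:0.3[&&NHX:age=2:S=MOUSE]):0.18[&&NHX:Ev=S:sos=0:age=2],(Phy002_PANTR:0.09[&&NHX:age=1:S=PANTR],Phy001_HUMAN:0.08[&&NHX:age=0:S=HUMAN]):0.2[&&NHX:Ev=S:sos=0:age=1]):0.675[&&NHX:Ev=D:sos=0.333333:age=2])[&&NHX:Ev=S:sos=0:age=3];
```

The tree is rooted on the YEAST edge (the taxonomically most distant
group). The node joining the (HUMAN, MOUSE) and (PANTR, HUMAN) clades has
overlap score 1/3 — HUMAN appears on both sides — so it is labeled a
duplication (`Ev=D`), dated to the Mammalia level (`age=2`).

```bash
$ phylomekit orthologs --tree labeled.nhx --seed Phy001_HUMAN --out calls.tsv
$ cat calls.tsv
seed_id	target_id	relation	type	score	n_trees
Phy001_HUMAN	Phy002_PANTR	ortholog	one-to-one
Phy001_HUMAN	Phy003_HUMAN	paralog
Phy001_HUMAN	Phy004_MOUSE	paralog
Phy001_HUMAN	Phy005_YEAST	ortholog	many-to-one
```

`Phy004_MOUSE` descends from the duplication, so it is a paralog of the
seed; the single YEAST gene is a many-to-one ortholog of the four
post-duplication copies. Reconciling the same tree confirms the event
count:

```bash
$ phylomekit reconcile --tree tree.nwk --species-tree species.nwk
duplications	1
losses	2
```

Other subcommands: `convert`, `consistency`, `gtp-search`, `rf`,
`conserved-pairs`, `trim` (alignment column filtering) and `simulate`
(species tree + duplication-loss gene tree + truth tables). All of them
are thin wrappers over the `phylomekit.*` modules, which are the primary
API.

## Limitations

The simulator covers duplication and loss only (no horizontal transfer or
incomplete lineage sorting), homology search / alignment / ML inference are
out of scope, and the exhaustive species-tree search refuses more than 8
species — use a heuristic searcher beyond that. See `docs/methods.md` for
the full model description and design rationale.
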