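# Methods

This note documents the models and procedures implemented in phylomekit,
the parameters that matter, the design choices made where the field leaves
room, and what the simulation-based tests do and do not establish.

## Data model and formats

Gene trees are rooted, possibly multifurcating trees whose leaves carry an
opaque sequence identifier and an uppercase species mnemonic, parsed from
the leaf label. The default naming convention takes the species as the
token after the *last* underscore (`Phy00086SJ_HUMAN`,
`my_gene_1_YEAST` → `my_gene_1` / `YEAST`); a prefix convention and a
regex convention (named groups `seq_id`, `species`) cover other corpora.
Duplicate `(seq_id, species)` pairs are rejected outright — silently
renaming them would corrupt downstream orthology tables.

Newick parsing is a small recursive-descent parser that reports the
0-based offset of any syntax error and preserves NHX comments. The NHX
vocabulary is `Ev` (D/S event), `S` (species), `sos` (overlap score),
`age` (relative-age index) and `B` (support). Numeric internal labels in
plain Newick are read as support values; non-numeric internal labels in
species trees are clade names (taxonomic levels). Branch lengths are
optional and `None` is distinct from zero — a missing length only matters
for midpoint rooting, which refuses to run without lengths. Writing uses
six decimal places for lengths; round trips preserve topology, labels and
annotations exactly (verified on 1000 simulated trees).

Nexus and PhyloXML are deliberately not supported; alignments are plain
FASTA with `-` as gap.

## Seed-relative rooting

Phylome trees are built per seed gene and analyzed from the seed's
perspective, so the root must separate the seed's closest relatives from
the most distant ones. The default `farthest_taxon` strategy scores every
candidate outgroup clade by the position of its *taxonomically closest*
member on the seed species' lineage (the ordered list of ancestor clades
from the seed species to the root of the reference species tree) and roots
on the edge of the deepest-scoring clade. Scoring a clade by its closest
member rather than by the LCA of the whole clade matters: a mixed clade
containing one near relative is a poor outgroup even if it also contains
distant species. Ties prefer larger clades, then the lexicographically
smallest leaf name, making the root deterministic.

A tree whose leaves all belong to one species has no taxonomic signal; it
falls back to midpoint rooting with a logged notice. Midpoint rooting
halves the longest leaf-to-leaf path (classic double-sweep) and places the
root fractionally along the crossing edge.

## Species-overlap event labeling

For a binary internal node with children species sets `A` and `B` the
overlap score is the Jaccard index `|A ∩ B| / |A ∪ B|`; multifurcating
nodes take the maximum over child pairs, the most duplication-sensitive
consistent extension. A node is a duplication iff its score strictly
exceeds the threshold, so the default threshold 0 classifies any shared
species as a duplication while keeping score-0 nodes speciations. The
normalization (union rather than smaller-set) and the strict inequality
are package decisions; both are exercised explicitly by tests at the
boundary.

The labeler requires a rooted tree (root with at most two children) and
errors otherwise rather than guessing a root.

Two provable properties anchor the tests:

- on loss-free simulations a true speciation node's children span disjoint
  species sets and a true duplication's children (absent loss) share at
  least one species, so threshold-0 labeling recovers the generating
  events exactly;
- any overlap implies the LCA mapping of some child equals the node's own
  mapping, so every species-overlap duplication is also an LCA
  reconciliation duplication (the converse is false — loss can hide
  duplications from the overlap rule).

## Phylostratigraphic ages

The lineage map of a seed species is the ordered list of strictly growing
clades from the seed leaf (level 0) to the root of the species tree. A
node's relative age is the smallest level whose species set contains every
species below the node. Ages are computed for all nodes — duplications,
speciations and leaves — and are non-decreasing toward the root by
construction. A species absent from the reference tree is a hard error:
dropping it silently would bias both overlap scores and ages.

## Orthology inference and typing

Relations follow the event at the pair's LCA; same-species pairs are
paralogs regardless of the labels above them (within-species copies are
in-paralogs by definition). Types count co-orthologs within the two child
clades of the relating node only — not across the whole tree — which keeps
typing local, deterministic and symmetric: swapping the pair transposes
one-to-many ↔ many-to-one.

The close2seed filter ranks non-seed leaves by nodal distance (edge count)
to the seed, breaking ties by branch-length distance and then sequence id.
The retained set is the top `k` plus the seed itself; by default the seed
does not consume one of the `k` slots (`include_seed=True` makes it
count, since usage varies). A call survives iff either member is retained.
Output order is preserved, so raising `k` strictly grows the output.

Consistency scores are the unweighted fraction of trees containing both
genes in which the pair is orthologous; pairs co-occurring in no tree are
omitted rather than scored 0, and the reported relation is the majority
vote with ties going to ortholog. No per-tree quality weighting is
applied.

`one_to_one_sets` builds the concatenation input: seed genes having
exactly one ortholog call, typed one-to-one, in every requested species.
The result is a pandas DataFrame (rows seeds, columns species, cells
ortholog ids); actual concatenation and ML inference are downstream tools'
business.

### OrthoXML

Export targets OrthoXML 0.3. Ortholog calls sharing a speciation node are
clustered; the cluster's genes are split into the node's two sides by
2-coloring the call graph, and each side with several genes becomes a
nested `paralogGroup`. If a call set is not closed under that cluster
structure (e.g. after close2seed filtering removed some cross pairs), the
writer falls back to one `orthologGroup` per pair so the document always
re-parses to exactly the input pair set. Mean consistency scores attach to
groups under a `consistency` score definition. The parser implements the
standard semantics — genes in different child subgroups of an
`orthologGroup` are orthologs — minus same-species combinations.

## Reconciliation and gene-tree parsimony

LCA reconciliation maps each gene-tree node to the species-tree LCA of its
descendant species; a node is a duplication iff its mapping equals at
least one child's mapping. Losses per gene-tree edge with species-path
length `d` count `d − 1` below a speciation and `d` below a duplication.
Multifurcating gene trees are refused here (resolve upstream); the
species-overlap path is the multifurcation-tolerant one. The default
parsimony cost is duplications plus losses; duplication-only is available
since phylome studies often use it.

The exhaustive search enumerates all `(2n−3)!!` rooted binary species
topologies (refusing `n > 8`) and scores each with a bitmask
implementation: species are bits, each gene tree is flattened once into
postorder merge instructions, and LCA lookups walk up from the lowest set
bit with memoization. A test pins this optimized scorer to the plain
per-tree reconciliation on every candidate topology. Ties are broken by
the lexicographically smallest Newick string and all co-optima are
reported. Heuristic (SPR/NNI) search for larger species sets is out of
scope.

## Tree and orthology-set comparison

Robinson–Foulds works on non-trivial unrooted bipartitions in canonical
form (each split stored as its lexicographically smaller side). The
normalized distance divides the symmetric difference by the total number
of non-trivial splits in both trees — equal to `2(n−3)` for two binary
trees, but still well-defined for multifurcations, which is why this
denominator was chosen. `strict` mode demands identical leaf sets;
`prune_to_shared` restricts both trees to their common leaves first
(at least 4), the mode needed when comparing tree versions across proteome
updates. Ortholog-pair conservation is `|intersection| / |reference|`
with the reference being either the first release or the union — both
options are exposed because either convention is defensible; identifier
mapping across releases is explicit caller input.

## Alignment column filtering

Alternative alignments of the same sequences (e.g. several aligners run
forward and on reversed sequences — heads-or-tails) vote on consensus
columns. A residue pair `(i, p, j, q)` (0-based ungapped positions) is
supported by an alternative iff that alignment places the two residues in
one column. Gap–residue and gap–gap cells carry no votes, and the
consensus does not vote for itself. A consensus-only pair therefore has
raw support 0; strict mode treats it like a singleton observation (the
column is dropped), and fraction mode counts it as 0 of `K`. Columns with
fewer than two residues have no pairs; their mean support is defined as
1.0 and they are always kept by strict mode.

Strict mode (default) drops any column containing a pair observed in at
most one underlying alignment; fraction mode drops columns whose mean
support `Σ support / (n_pairs · K)` falls below `min_fraction` (default
0.5). Filtering only removes columns — per-row residues concatenate to a
subsequence of the original sequence — and is idempotent once the
alternatives are re-projected onto the kept residues
(`kept_residues` / `restrict_to_residues` implement the projection).
Reversed alignments must be re-reversed by the caller; orientation is
validated by exact ungapped-sequence equality, never guessed.

Consensus construction itself (M-Coffee-style) and trimAl's other trimming
modes are out of scope; the consensus is an input.

## Simulator

`simulate_species_tree` draws a Yule tree: lineages split uniformly at
random with exponential waiting times, pendant branches extend to a final
sampling time, and all heights are scaled so the root-to-tip span is 1.
Species are named `SP001…` in leaf order.

`simulate_gene_tree` walks one gene lineage down the species tree:
duplications arrive at rate λ and losses at rate μ per lineage per unit
branch length; at species splits the lineage enters both child branches.
Events are logged on the surviving nodes at generation time — never
re-inferred — so evaluations against this truth are circularity-free.
Lost subtrees are pruned and pass-through nodes collapsed, emulating the
missing-gene noise of low-coverage or transcriptome-derived proteomes. An
optional stem above the species root (default length 0) lets duplications
predate the root, producing out-paralog structure for age tests. All
randomness flows from a single integer seed; identical seeds give
byte-identical Newick output.

`true_orthologs` reads pairs off the logged events (LCA speciation ⇔
ortholog), giving the ground truth for precision/recall.

What the simulator does *not* model: sequence evolution (no alignments or
inference error on topologies), horizontal transfer and incomplete lineage
sorting. Passing the recovery tests therefore shows the inference chain is
correct *given a correct tree*, not that real trees are this clean.

## Test and acceptance conditions

The acceptance checks run at these problem sizes, chosen to exercise the
asymptotic claims while keeping a laptop-scale runtime: 1000 loss-free
gene families with λ ∈ {0.1, 0.5, 1.0} over 5–15 Yule species (event and
orthology recovery must be exact); 500 families at μ = 0.3 (recall is
reported; mean per-tree precision must stay ≥ 0.95 — in practice it sits
near 0.999 because a duplication only becomes invisible when
complementary losses leave its children species-disjoint); 1000 mixed-rate
families for the overlap ⊆ LCA duplication subset property; 10 000 random
tree pairs (≤ 8 leaves) against a brute-force split-enumeration RF oracle;
100 batches of 50 duplication-free families over 5 species for exhaustive
species-tree recovery at cost 0 (duplication-free because any duplication
adds its own cost at the true tree, making "cost 0" the right criterion
only in this regime); a 41-leaf caterpillar for the exact close2seed
contract and its monotonicity in k; 200 random alignment bundles (≤ 5
sequences, ≤ 30 columns, K ∈ 2..6) against a residue-pair-table oracle;
and 1000 annotated Newick plus 50 OrthoXML round trips.

`scripts/acceptance.py` recomputes all of these from a single `--seed` and
writes the resulting rates and counts as JSON; the unit suite asserts the
same properties independently.

## Known limitations

- The species-overlap score normalizes by the union; tools normalizing by
  the smaller child set will score multifurcation-heavy trees differently.
- close2seed ranks purely by nodal distance (ties by branch length);
  alternative rankings (e.g. pure branch length) are not offered.
- The OrthoXML writer targets version 0.3 structure but does not validate
  against the XSD.
- `search_species_trees` is exact but exponential; 8 species ≈ 135 135
  topologies is the practical ceiling.
- Consistency scoring treats all trees equally; no support- or
  quality-based weighting.
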