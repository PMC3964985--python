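"""Tree-based orthology/paralogy inference, close2seed filtering,
cross-tree consistency scores and OrthoXML/TSV export.

Two genes are orthologs when the event at their last common ancestor in a
labeled gene tree is a speciation, paralogs when it is a duplication (genes
from the same species are always paralogs).  Ortholog calls are typed
one-to-one / one-to-many / many-to-one / many-to-many by counting
co-orthologs inside the two child clades of the relating node.

The close2seed filter keeps only predictions in which at least one member
belongs to the k sequences nodally closest to the seed (default k=30), the
regime in which seed-tree signal dominates collateral-tree noise.

Consistency scores follow the MetaPhOrs idea: the fraction of trees
containing both genes in which the pair is orthologous.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, replace

import pandas as pd
from lxml import etree

from .events import branch_length_distance
from .treeio import GeneTree, TreeError, TreeNode

ORTHOLOG = "ortholog"
PARALOG = "paralog"

ONE_TO_ONE = "one-to-one"
ONE_TO_MANY = "one-to-many"
MANY_TO_ONE = "many-to-one"
MANY_TO_MANY = "many-to-many"

_ORTHOXML_NS = "http://orthoXML.org/2011/"


@dataclass(frozen=True, order=True)
class Gene:
    seq_id: str
    species: str

    def __str__(self) -> str:
        return f"{self.seq_id}_{self.species}"


@dataclass
class OrthologyCall:
    gene_a: Gene
    gene_b: Gene
    relation: str
    type: str | None = None
    lca_id: int | None = None
    consistency_score: float | None = None
    n_trees: int | None = None

    def pair_key(self) -> frozenset[Gene]:
        return frozenset((self.gene_a, self.gene_b))

    def swapped(self) -> "OrthologyCall":
        transpose = {ONE_TO_MANY: MANY_TO_ONE, MANY_TO_ONE: ONE_TO_MANY}
        return replace(
            self,
            gene_a=self.gene_b,
            gene_b=self.gene_a,
            type=transpose.get(self.type, self.type),
        )


@dataclass(frozen=True)
class Close2SeedConfig:
    k: int = 30
    distance: str = "nodal"
    include_seed: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("close2seed k must be >= 1")
        if self.distance != "nodal":
            raise ValueError(f"unsupported distance {self.distance!r}")


def _gene(leaf: TreeNode) -> Gene:
    return Gene(leaf.seq_id or leaf.name, leaf.species)


def _require_labeled(tree: GeneTree) -> None:
    if not tree.is_labeled():
        raise TreeError(
            "gene tree is not event-labeled; run events.label_events first"
        )


def _lca_table(root: TreeNode):
    depth: dict[int, int] = {}
    for node in root.traverse():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1

    def lca_with_children(a: TreeNode, b: TreeNode):
        """LCA of two leaves plus the LCA children leading to each."""
        ca, cb = a, b
        da, db = depth[id(a)], depth[id(b)]
        while da > db:
            ca, da = ca.parent, da - 1
        while db > da:
            cb, db = cb.parent, db - 1
        prev_a, prev_b = ca, cb
        while ca is not cb:
            prev_a, prev_b = ca, cb
            ca, cb = ca.parent, cb.parent
        return ca, prev_a, prev_b

    return lca_with_children


def infer_orthology(
    tree: GeneTree,
    seed_leaf=None,
    all_vs_all: bool = False,
) -> list[OrthologyCall]:
    """Derive orthology/paralogy calls from an event-labeled gene tree.

    With ``seed_leaf`` only pairs containing the seed are emitted; with
    ``all_vs_all`` every leaf pair is classified.  Exactly one relation is
    produced per pair.
    """
    _require_labeled(tree)
    if not all_vs_all and seed_leaf is None:
        raise ValueError("provide seed_leaf or set all_vs_all=True")
    leaves = tree.leaves()
    lca_with_children = _lca_table(tree.root)
    side_leaves: dict[int, list[TreeNode]] = {}

    def leaves_under(node: TreeNode) -> list[TreeNode]:
        if id(node) not in side_leaves:
            side_leaves[id(node)] = node.leaves()
        return side_leaves[id(node)]

    if all_vs_all:
        pairs = list(itertools.combinations(leaves, 2))
    else:
        seed = tree.find_leaf(seed_leaf)
        pairs = [(seed, leaf) for leaf in leaves if leaf is not seed]

    calls: list[OrthologyCall] = []
    for a, b in pairs:
        ga, gb = _gene(a), _gene(b)
        lca, child_a, child_b = lca_with_children(a, b)
        if ga.species == gb.species or lca.event != "speciation":
            calls.append(OrthologyCall(ga, gb, PARALOG, lca_id=id(lca)))
            continue
        n_a = sum(
            1 for x in leaves_under(child_a) if x.species != gb.species
        )
        n_b = sum(
            1 for y in leaves_under(child_b) if y.species != ga.species
        )
        if n_a == 1 and n_b == 1:
            otype = ONE_TO_ONE
        elif n_a == 1:
            otype = ONE_TO_MANY
        elif n_b == 1:
            otype = MANY_TO_ONE
        else:
            otype = MANY_TO_MANY
        calls.append(OrthologyCall(ga, gb, ORTHOLOG, otype, lca_id=id(lca)))
    return calls


# ---------------------------------------------------------------------------
# close2seed


def rank_leaves_by_seed_distance(tree: GeneTree, seed_leaf) -> list[TreeNode]:
    """Non-seed leaves ordered by nodal distance to the seed.

    Ties are broken by branch-length distance, then by seq_id, so the
    ranking is deterministic.
    """
    seed = tree.find_leaf(seed_leaf)
    nodal = _nodal_distances_from(tree.root, seed)
    ranked = [leaf for leaf in tree.leaves() if leaf is not seed]
    ranked.sort(
        key=lambda leaf: (
            nodal[id(leaf)],
            branch_length_distance(tree, seed, leaf),
            leaf.seq_id or leaf.name,
        )
    )
    return ranked


def _nodal_distances_from(root: TreeNode, start: TreeNode) -> dict[int, int]:
    adj: dict[int, list[TreeNode]] = defaultdict(list)
    for node in root.traverse():
        for child in node.children:
            adj[id(node)].append(child)
            adj[id(child)].append(node)
    dist = {id(start): 0}
    queue = [start]
    while queue:
        node = queue.pop(0)
        for nbr in adj[id(node)]:
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(node)] + 1
                queue.append(nbr)
    return dist


def apply_close2seed(
    calls: list[OrthologyCall],
    tree: GeneTree,
    seed_leaf,
    cfg: Close2SeedConfig | None = None,
) -> list[OrthologyCall]:
    """Retain calls touching the k leaves nodally closest to the seed.

    The seed itself is always part of the retained set; by default it does
    not consume one of the k slots (``cfg.include_seed`` makes it count).
    """
    cfg = cfg or Close2SeedConfig()
    seed = tree.find_leaf(seed_leaf)
    k = cfg.k - 1 if cfg.include_seed else cfg.k
    ranked = rank_leaves_by_seed_distance(tree, seed)
    kept_genes = {_gene(seed)} | {_gene(leaf) for leaf in ranked[:k]}
    return [
        call
        for call in calls
        if call.gene_a in kept_genes or call.gene_b in kept_genes
    ]


# ---------------------------------------------------------------------------
# Consistency scores across a tree collection


def consistency_scores(
    trees: list[GeneTree],
    pairs: list[tuple] | None = None,
) -> list[OrthologyCall]:
    """Score gene pairs by the fraction of trees calling them orthologs.

    ``pairs`` items are ``(Gene, Gene)`` or ``((seq_id, species), ...)``
    tuples; with ``pairs=None`` every pair co-occurring in at least one tree
    is scored.  Pairs found in no tree are omitted.  The reported relation
    is the majority vote (ties go to ortholog).
    """
    if not trees:
        raise ValueError("empty tree collection")
    for tree in trees:
        _require_labeled(tree)

    indexed = []
    for tree in trees:
        leaf_map = {_gene(leaf): leaf for leaf in tree.leaves()}
        indexed.append((tree, leaf_map, _lca_table(tree.root)))

    if pairs is None:
        universe: set[frozenset[Gene]] = set()
        for _, leaf_map, _ in indexed:
            for ga, gb in itertools.combinations(sorted(leaf_map), 2):
                universe.add(frozenset((ga, gb)))
        todo = [tuple(sorted(p)) for p in universe]
        todo.sort()
    else:
        todo = []
        for a, b in pairs:
            ga = a if isinstance(a, Gene) else Gene(*a)
            gb = b if isinstance(b, Gene) else Gene(*b)
            todo.append((ga, gb))

    out: list[OrthologyCall] = []
    for ga, gb in todo:
        n = 0
        n_orth = 0
        for _, leaf_map, lca_fn in indexed:
            if ga not in leaf_map or gb not in leaf_map:
                continue
            n += 1
            lca, _, _ = lca_fn(leaf_map[ga], leaf_map[gb])
            if lca.event == "speciation" and ga.species != gb.species:
                n_orth += 1
        if n == 0:
            continue
        score = n_orth / n
        relation = ORTHOLOG if score >= 0.5 else PARALOG
        out.append(
            OrthologyCall(
                ga, gb, relation, consistency_score=score, n_trees=n
            )
        )
    return out


# ---------------------------------------------------------------------------
# One-to-one ortholog matrix (concatenation input)


def one_to_one_sets(
    calls_by_seed: dict[Gene, list[OrthologyCall]],
    species: list[str],
) -> pd.DataFrame:
    """Matrix of seed genes with exactly one one-to-one ortholog per species.

    Rows are seed genes (index = seed seq_id), columns the requested species,
    cells the unique ortholog's seq_id — the input for downstream
    concatenation.  Seeds failing the one-to-one requirement in any listed
    species are excluded.
    """
    if not species:
        raise ValueError("empty species list")
    rows = {}
    for seed, calls in sorted(calls_by_seed.items()):
        row = {}
        for sp in species:
            hits = [
                c
                for c in calls
                if c.relation == ORTHOLOG
                and (c.gene_b.species == sp or c.gene_a.species == sp)
            ]
            if len(hits) != 1 or hits[0].type != ONE_TO_ONE:
                row = None
                break
            hit = hits[0]
            other = hit.gene_b if hit.gene_b.species == sp else hit.gene_a
            row[sp] = other.seq_id
        if row is not None:
            rows[seed.seq_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=species)


# ---------------------------------------------------------------------------
# OrthoXML export / import


def write_orthoxml(
    calls: list[OrthologyCall],
    database: str = "phylomekit",
    version: str = "0.1",
    known_species: set[str] | None = None,
) -> str:
    """Serialize ortholog calls as an OrthoXML 0.3 document.

    Calls sharing a speciation node are merged into one orthologGroup whose
    two sides become nested paralogGroups when they hold several in-paralogs;
    call sets that do not form such a closed cluster fall back to one group
    per pair.  Consistency scores, when present, are attached to groups.
    """
    if not calls:
        raise ValueError("cannot write OrthoXML for an empty call list")
    ortho_calls = [c for c in calls if c.relation == ORTHOLOG]
    if not ortho_calls:
        raise ValueError("no ortholog calls to export")
    genes = sorted({g for c in ortho_calls for g in (c.gene_a, c.gene_b)})
    if known_species is not None:
        unknown = sorted({g.species for g in genes} - known_species)
        if unknown:
            raise ValueError(f"calls reference unknown species: {unknown}")
    gene_ids = {g: str(i + 1) for i, g in enumerate(genes)}

    nsmap = {None: _ORTHOXML_NS}
    root = etree.Element(
        f"{{{_ORTHOXML_NS}}}orthoXML",
        nsmap=nsmap,
        version="0.3",
        origin=database,
        originVersion=version,
    )
    by_species: dict[str, list[Gene]] = defaultdict(list)
    for g in genes:
        by_species[g.species].append(g)
    for sp in sorted(by_species):
        sp_el = etree.SubElement(
            root, f"{{{_ORTHOXML_NS}}}species", name=sp, NCBITaxId="0"
        )
        db_el = etree.SubElement(
            sp_el, f"{{{_ORTHOXML_NS}}}database", name=database, version=version
        )
        genes_el = etree.SubElement(db_el, f"{{{_ORTHOXML_NS}}}genes")
        for g in by_species[sp]:
            etree.SubElement(
                genes_el,
                f"{{{_ORTHOXML_NS}}}gene",
                id=gene_ids[g],
                protId=g.seq_id,
            )
    scores_el = etree.SubElement(root, f"{{{_ORTHOXML_NS}}}scores")
    etree.SubElement(
        scores_el,
        f"{{{_ORTHOXML_NS}}}scoreDef",
        id="consistency",
        desc="fraction of trees supporting orthology",
    )
    groups_el = etree.SubElement(root, f"{{{_ORTHOXML_NS}}}groups")

    gid = itertools.count(1)
    for cluster in _clusters(ortho_calls):
        sides = _two_color(cluster)
        if sides is not None and _closure_matches(cluster, sides):
            _emit_group(groups_el, gid, sides, cluster, gene_ids)
        else:
            for call in cluster:
                _emit_group(
                    groups_el,
                    gid,
                    ({call.gene_a}, {call.gene_b}),
                    [call],
                    gene_ids,
                )
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode()


def _clusters(calls: list[OrthologyCall]) -> list[list[OrthologyCall]]:
    grouped: dict = defaultdict(list)
    for i, call in enumerate(calls):
        key = call.lca_id if call.lca_id is not None else ("pair", i)
        grouped[key].append(call)
    return [grouped[k] for k in sorted(grouped, key=str)]


def _two_color(cluster: list[OrthologyCall]):
    """Split a cluster's genes into the two sides of its speciation node."""
    adj: dict[Gene, set[Gene]] = defaultdict(set)
    for call in cluster:
        adj[call.gene_a].add(call.gene_b)
        adj[call.gene_b].add(call.gene_a)
    color: dict[Gene, int] = {}
    for start in sorted(adj):
        if start in color:
            continue
        color[start] = 0
        queue = [start]
        while queue:
            node = queue.pop(0)
            for nbr in adj[node]:
                if nbr not in color:
                    color[nbr] = 1 - color[node]
                    queue.append(nbr)
                elif color[nbr] == color[node]:
                    return None
    side0 = {g for g, c in color.items() if c == 0}
    side1 = {g for g, c in color.items() if c == 1}
    return side0, side1


def _closure_matches(cluster, sides) -> bool:
    side0, side1 = sides
    closure = {
        frozenset((a, b))
        for a in side0
        for b in side1
        if a.species != b.species
    }
    return closure == {c.pair_key() for c in cluster}


def _emit_group(groups_el, gid, sides, cluster, gene_ids) -> None:
    group = etree.SubElement(
        groups_el, f"{{{_ORTHOXML_NS}}}orthologGroup", id=str(next(gid))
    )
    scores = [
        c.consistency_score for c in cluster if c.consistency_score is not None
    ]
    if scores:
        etree.SubElement(
            group,
            f"{{{_ORTHOXML_NS}}}score",
            id="consistency",
            value=f"{sum(scores) / len(scores):.6g}",
        )
    for side in sides:
        members = sorted(side)
        if len(members) == 1:
            etree.SubElement(
                group,
                f"{{{_ORTHOXML_NS}}}geneRef",
                id=gene_ids[members[0]],
            )
        else:
            para = etree.SubElement(group, f"{{{_ORTHOXML_NS}}}paralogGroup")
            for g in members:
                etree.SubElement(
                    para, f"{{{_ORTHOXML_NS}}}geneRef", id=gene_ids[g]
                )


def parse_orthoxml(document: str | bytes) -> set[frozenset[Gene]]:
    """Extract the ortholog pair set encoded by an OrthoXML document.

    Pairs are all cross products between the child subgroups of each
    orthologGroup, excluding same-species combinations (those are
    in-paralogs by construction).
    """
    if isinstance(document, str):
        document = document.encode()
    root = etree.fromstring(document)
    ns = {"o": _ORTHOXML_NS}
    id_to_gene: dict[str, Gene] = {}
    for sp_el in root.findall("o:species", ns):
        species = sp_el.get("name")
        for gene_el in sp_el.findall(".//o:gene", ns):
            id_to_gene[gene_el.get("id")] = Gene(gene_el.get("protId"), species)

    pairs: set[frozenset[Gene]] = set()

    def genes_of(elem) -> set[Gene]:
        out: set[Gene] = set()
        for child in elem:
            tag = etree.QName(child).localname
            if tag == "geneRef":
                out.add(id_to_gene[child.get("id")])
            elif tag in ("paralogGroup", "orthologGroup"):
                out |= genes_of(child)
        return out

    def walk(group) -> None:
        subgroups = []
        for child in group:
            tag = etree.QName(child).localname
            if tag == "geneRef":
                subgroups.append({id_to_gene[child.get("id")]})
            elif tag in ("paralogGroup", "orthologGroup"):
                subgroups.append(genes_of(child))
                if tag == "orthologGroup":
                    walk(child)
        for sa, sb in itertools.combinations(subgroups, 2):
            for a in sa:
                for b in sb:
                    if a.species != b.species:
                        pairs.add(frozenset((a, b)))

    groups = root.find("o:groups", ns)
    if groups is not None:
        for group in groups.findall("o:orthologGroup", ns):
            walk(group)
    return pairs


# ---------------------------------------------------------------------------
# Tabular export


def write_tsv(calls: list[OrthologyCall], handle) -> None:
    """Write calls as TSV: seed_id, target_id, relation, type, score, n_trees."""
    handle.write("seed_id\ttarget_id\trelation\ttype\tscore\tn_trees\n")
    for call in sorted(calls, key=lambda c: (str(c.gene_a), str(c.gene_b))):
        score = (
            f"{call.consistency_score:.6g}"
            if call.consistency_score is not None
            else ""
        )
        n_trees = str(call.n_trees) if call.n_trees is not None else ""
        handle.write(
            f"{call.gene_a}\t{call.gene_b}\t{call.relation}\t"
            f"{call.type or ''}\t{score}\t{n_trees}\n"
        )


def read_pairs_tsv(handle) -> list[tuple[Gene, Gene]]:
    """Read gene pairs from a TSV whose first two columns are seqid_SPECIES."""
    from .treeio import parse_leaf_name

    pairs = []
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("seed_id"):
            continue
        a, b = line.split("\t")[:2]
        pairs.append((Gene(*parse_leaf_name(a)), Gene(*parse_leaf_name(b))))
    return pairs
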