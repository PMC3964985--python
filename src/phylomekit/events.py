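"""Seed-relative rooting, species-overlap event labeling and node dating.

The species-overlap rule labels an internal node a *duplication* when the
species sets of its children overlap beyond a threshold, and a *speciation*
otherwise.  The overlap score of a binary node is the Jaccard index of its
two children's species sets; multifurcations take the maximum over child
pairs.  With the default threshold of 0 any shared species marks a
duplication.

Relative ages (phylostratigraphy) date a node by the smallest taxonomic
level on the seed species' lineage that contains all species below the node.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from .treeio import (
    GeneTree,
    SpeciesTree,
    TreeError,
    TreeNode,
    reroot_on_edge,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Phylostratigraphic lineage


@dataclass(frozen=True)
class LineageLevel:
    name: str
    species: frozenset[str]


@dataclass(frozen=True)
class LineageMap:
    """Ordered taxonomic levels from a seed species up to the root.

    Level 0 holds exactly the seed species; each subsequent level is an
    ancestor clade of the species tree, so the species sets are strictly
    nested and increasing.
    """

    seed_species: str
    levels: tuple[LineageLevel, ...]

    @classmethod
    def from_species_tree(
        cls, species_tree: SpeciesTree, seed_species: str
    ) -> "LineageMap":
        if seed_species not in species_tree.leaf_map:
            raise TreeError(
                f"seed species {seed_species!r} absent from species tree"
            )
        node = species_tree.leaf_map[seed_species]
        levels = []
        index = 0
        while node is not None:
            sp = node.species_set()
            if not levels or sp != levels[-1].species:
                name = node.name if node.name else f"level{index}"
                levels.append(LineageLevel(name, sp))
                index += 1
            node = node.parent
        return cls(seed_species, tuple(levels))

    def level_of(self, species: frozenset[str] | set[str]) -> int:
        """Smallest level index whose species set contains ``species``."""
        species = frozenset(species)
        for i, level in enumerate(self.levels):
            if species <= level.species:
                return i
        missing = sorted(species - self.levels[-1].species)
        raise TreeError(
            "species outside every lineage level: " + ", ".join(missing)
        )


# ---------------------------------------------------------------------------
# Rooting


def root_tree(
    tree: GeneTree,
    species_tree: SpeciesTree | None = None,
    seed_leaf=None,
    strategy: str = "farthest_taxon",
) -> GeneTree:
    """Return a copy of ``tree`` rooted for seed-centric analysis.

    ``farthest_taxon`` places the root on the edge of the monophyletic group
    that is taxonomically most distant from the seed species: the group whose
    *closest* member sits deepest on the seed lineage.  Ties prefer larger
    clades, then the lexicographically smallest leaf name.  A tree whose
    leaves all share one species falls back to midpoint rooting.

    ``midpoint`` halves the longest leaf-to-leaf path (requires branch
    lengths).
    """
    work = tree.copy()
    leaves = work.leaves()
    if len(leaves) < 2:
        raise TreeError("cannot root a tree with fewer than 2 leaves")
    if len(leaves) == 2:
        return work  # single internal edge; the root is forced

    if strategy == "midpoint":
        return GeneTree(_midpoint_root(work.root), naming=work.naming)
    if strategy != "farthest_taxon":
        raise ValueError(f"unknown rooting strategy {strategy!r}")

    if species_tree is None or seed_leaf is None:
        raise TreeError("farthest_taxon rooting needs species_tree and seed_leaf")
    species_tree.check_species(work.species_set)
    seed = work.find_leaf(seed_leaf)
    if len(work.species_set) == 1:
        logger.info(
            "all leaves share species %s; falling back to midpoint rooting",
            seed.species,
        )
        return GeneTree(_midpoint_root(work.root), naming=work.naming)

    lineage = LineageMap.from_species_tree(species_tree, seed.species)
    root = reroot_on_edge(work.root, seed)

    best = None
    best_key = None
    for node in root.traverse():
        if node is root or node is seed:
            continue
        sp = node.species_set()
        # distance of the clade = lineage depth of its taxonomically
        # closest member; a clean outgroup maximizes it
        depth = min(lineage.level_of({s}) for s in sp)
        node_leaves = node.leaves()
        key = (
            depth,
            len(node_leaves),
            _NegStr(min(leaf.name or "" for leaf in node_leaves)),
        )
        if best_key is None or key > best_key:
            best, best_key = node, key
    new_root = reroot_on_edge(root, best)
    return GeneTree(new_root, naming=work.naming)


class _NegStr:
    """Orders strings in reverse, so max() prefers the smallest name."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __gt__(self, other: "_NegStr") -> bool:
        return self.s < other.s

    def __eq__(self, other) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


def _adjacency(root: TreeNode) -> dict[int, list[tuple[TreeNode, float]]]:
    adj: dict[int, list[tuple[TreeNode, float]]] = {}
    for node in root.traverse():
        for child in node.children:
            if child.branch_length is None:
                raise TreeError(
                    "midpoint rooting requires branch lengths on every edge"
                )
            adj.setdefault(id(node), []).append((child, child.branch_length))
            adj.setdefault(id(child), []).append((node, child.branch_length))
    return adj


def _farthest(start: TreeNode, adj) -> tuple[TreeNode, dict[int, float], dict[int, TreeNode]]:
    dist = {id(start): 0.0}
    pred: dict[int, TreeNode] = {}
    stack = [start]
    far = start
    while stack:
        node = stack.pop()
        for nbr, w in adj.get(id(node), []):
            if id(nbr) not in dist:
                dist[id(nbr)] = dist[id(node)] + w
                pred[id(nbr)] = node
                stack.append(nbr)
                if nbr.is_leaf and dist[id(nbr)] > dist[id(far)]:
                    far = nbr
    return far, dist, pred


def _midpoint_root(root: TreeNode) -> TreeNode:
    adj = _adjacency(root)
    any_leaf = next(n for n in root.traverse() if n.is_leaf)
    u, _, _ = _farthest(any_leaf, adj)
    v, dist, pred = _farthest(u, adj)
    total = dist[id(v)]
    # path u -> v via predecessors of the sweep from u
    path = [v]
    while path[-1] is not u:
        path.append(pred[id(path[-1])])
    path.reverse()
    half = total / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        length = next(w for nbr, w in adj[id(a)] if nbr is b)
        if acc + length >= half or (a, b) == (path[-2], path[-1]):
            into = half - acc  # distance from a toward b
            child = b if b.parent is a else a
            if length == 0:
                frac = 0.5
            elif child is b:
                frac = (length - into) / length
            else:
                frac = into / length
            frac = min(1.0, max(0.0, frac))
            return reroot_on_edge(root, child, outgroup_fraction=frac)
        acc += length
    raise AssertionError("midpoint edge not found")  # pragma: no cover


# ---------------------------------------------------------------------------
# Species-overlap labeling


def label_events(tree: GeneTree, threshold: float = 0.0) -> GeneTree:
    """Label every internal node duplication/speciation by species overlap.

    Mutates ``tree`` in place and returns it.  A node is a duplication iff
    its overlap score strictly exceeds ``threshold`` (so threshold 0 means
    any shared species implies duplication).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    if len(tree.root.children) > 2:
        raise TreeError(
            "tree looks unrooted (root has more than 2 children); "
            "call root_tree first"
        )
    species: dict[int, frozenset[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            species[id(node)] = frozenset([node.species])
            continue
        child_sets = [species[id(c)] for c in node.children]
        species[id(node)] = frozenset().union(*child_sets)
        score = max(
            _jaccard(a, b) for a, b in itertools.combinations(child_sets, 2)
        )
        node.overlap_score = score
        node.event = "duplication" if score > threshold else "speciation"
    return tree


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


# ---------------------------------------------------------------------------
# Nodal distance


def nodal_distance(tree: GeneTree, leaf_a, leaf_b) -> int:
    """Number of edges on the path between two leaves (topology only)."""
    a = tree.find_leaf(leaf_a)
    b = tree.find_leaf(leaf_b)
    if a is b:
        return 0
    depth: dict[int, int] = {}
    for node in tree.root.traverse():
        depth[id(node)] = 0 if node.parent is None else depth[id(node.parent)] + 1
    da, db = depth[id(a)], depth[id(b)]
    x, y, steps = a, b, 0
    while da > db:
        x, da, steps = x.parent, da - 1, steps + 1
    while db > da:
        y, db, steps = y.parent, db - 1, steps + 1
    while x is not y:
        x, y, steps = x.parent, y.parent, steps + 2
    return steps


def branch_length_distance(tree: GeneTree, leaf_a, leaf_b) -> float:
    """Sum of branch lengths along the path (missing lengths count as 0)."""
    a = tree.find_leaf(leaf_a)
    b = tree.find_leaf(leaf_b)
    if a is b:
        return 0.0
    anc_a = {id(n): i for i, n in enumerate([a] + a.ancestors())}
    chain_b = [b] + b.ancestors()
    lca = next(n for n in chain_b if id(n) in anc_a)
    total = 0.0
    for start in (a, b):
        node = start
        while node is not lca:
            total += node.branch_length or 0.0
            node = node.parent
    return total


# ---------------------------------------------------------------------------
# Relative ages


def assign_relative_ages(tree: GeneTree, lineage: LineageMap) -> GeneTree:
    """Assign a phylostratigraphic age index to every node of ``tree``.

    The age of a node is the smallest lineage level whose species set
    contains all species below it; ages are therefore non-decreasing toward
    the root.  Mutates in place and returns ``tree``.
    """
    species: dict[int, frozenset[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            species[id(node)] = frozenset([node.species])
        else:
            species[id(node)] = frozenset().union(
                *(species[id(c)] for c in node.children)
            )
        node.age_index = lineage.level_of(species[id(node)])
    return tree
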