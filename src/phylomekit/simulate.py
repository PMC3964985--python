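"""Duplication–loss gene-tree simulation with ground-truth event logs.

A Yule species tree (unit depth) hosts a birth–death gene-family walk: one
gene lineage enters at the root and travels down every species branch,
duplicating at rate ``dup_rate`` and dying at rate ``loss_rate`` (both per
lineage per unit branch length).  At species-tree splits the lineage enters
both child branches (a speciation node); survivors at the species leaves
become gene-tree leaves.  Every surviving internal node carries its true
event, logged at generation time, so downstream labeling and orthology
inference can be evaluated without circularity.  Losses silently prune
subtrees, emulating the missing-gene noise of low-coverage proteomes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .orthology import Gene
from .treeio import GeneTree, SpeciesTree, TreeError, TreeNode


@dataclass
class SimRecord:
    """A simulated gene tree plus its ground truth.

    ``gene_tree`` is ``None`` when the whole family went extinct.
    ``true_events`` maps each surviving internal node to its generating
    event; ``loss_events`` lists the species-tree branches (as sorted
    species tuples) on which a lineage died.
    """

    gene_tree: GeneTree | None
    true_events: dict[TreeNode, str]
    loss_events: list[tuple[str, ...]]
    params: dict


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_species_tree(n_species: int, rng_seed) -> SpeciesTree:
    """Yule (pure-birth) species tree with unit root-to-tip depth.

    Lineages split uniformly at random with exponential waiting times;
    species are named SP001, SP002, ... in leaf order.  Deterministic for a
    given seed.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _rng(rng_seed)
    root = TreeNode()
    birth: dict[int, float] = {id(root): 0.0}
    split: dict[int, float] = {}
    tips = [root]
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / len(tips))
        node = tips.pop(int(rng.integers(len(tips))))
        split[id(node)] = t
        for _ in range(2):
            child = node.add_child(TreeNode())
            birth[id(child)] = t
            tips.append(child)
    t_end = t + rng.exponential(1.0 / n_species)
    depth = t_end - split[id(root)]  # root-to-tip time span
    for node in root.traverse():
        if node.parent is None:
            continue
        end = split[id(node)] if node.children else t_end
        node.branch_length = (end - birth[id(node)]) / depth
    for i, leaf in enumerate(root.leaves(), start=1):
        leaf.name = f"SP{i:03d}"
    return SpeciesTree(root)


def simulate_gene_tree(
    species_tree: SpeciesTree,
    dup_rate: float,
    loss_rate: float,
    rng_seed,
    root_edge_length: float = 0.0,
) -> SimRecord:
    """Birth–death walk of one gene lineage down a species tree.

    ``root_edge_length`` adds a stem above the species root on which
    pre-root duplications (out-paralogs) can occur.  Deterministic for a
    given seed.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    for node in species_tree.root.traverse():
        if node.parent is not None and node.branch_length is None:
            raise TreeError("species tree must have branch lengths")
    rng = _rng(rng_seed)
    total_rate = dup_rate + loss_rate
    counter = itertools.count(1)
    loss_events: list[tuple[str, ...]] = []

    def evolve(sp_node: TreeNode, remaining: float) -> TreeNode | None:
        consumed = 0.0
        branch_label = tuple(sorted(sp_node.species_set()))
        while True:
            wait = (
                rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            )
            if wait >= remaining:
                consumed += remaining
                break
            remaining -= wait
            consumed += wait
            if total_rate > 0 and rng.random() < dup_rate / total_rate:
                left = evolve(sp_node, remaining)
                right = evolve(sp_node, remaining)
                if left is None and right is None:
                    return None
                if left is None or right is None:
                    survivor = left if left is not None else right
                    survivor.branch_length += consumed
                    return survivor
                node = TreeNode(branch_length=consumed)
                node.true_event = "duplication"
                node.add_child(left)
                node.add_child(right)
                return node
            loss_events.append(branch_label)
            return None
        if sp_node.is_leaf:
            leaf = TreeNode(
                name=f"g{next(counter):04d}_{sp_node.name}",
                branch_length=consumed,
            )
            leaf.seq_id, _, leaf.species = leaf.name.rpartition("_")
            return leaf
        kids = [evolve(c, c.branch_length) for c in sp_node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].branch_length += consumed
            return kids[0]
        node = TreeNode(branch_length=consumed)
        node.true_event = "speciation"
        for k in kids:
            node.add_child(k)
        return node

    root = evolve(species_tree.root, root_edge_length)
    params = {
        "dup_rate": dup_rate,
        "loss_rate": loss_rate,
        "root_edge_length": root_edge_length,
    }
    if root is None:
        return SimRecord(None, {}, loss_events, params)
    root.branch_length = None
    tree = GeneTree(root)
    true_events = {
        node: node.true_event
        for node in root.traverse()
        if not node.is_leaf
    }
    return SimRecord(tree, true_events, loss_events, params)


def simulate_gene_family(
    species_tree: SpeciesTree,
    dup_rate: float,
    loss_rate: float,
    rng_seed: int,
    min_leaves: int = 2,
    max_tries: int = 1000,
    root_edge_length: float = 0.0,
) -> SimRecord:
    """Like :func:`simulate_gene_tree` but retries until >= ``min_leaves``.

    Retries draw fresh seeds deterministically from ``rng_seed``, so loss
    regimes that occasionally extinguish the family still yield usable
    records.
    """
    seeder = np.random.default_rng(rng_seed)
    for _ in range(max_tries):
        rec = simulate_gene_tree(
            species_tree,
            dup_rate,
            loss_rate,
            int(seeder.integers(2**31)),
            root_edge_length=root_edge_length,
        )
        if rec.gene_tree is not None and len(rec.gene_tree.leaves()) >= min_leaves:
            return rec
    raise RuntimeError(
        f"no surviving family with >= {min_leaves} leaves in {max_tries} tries"
    )


def random_rooted_tree(leaf_names: list[str], rng_seed) -> GeneTree:
    """Uniform-ish random rooted binary tree over the given leaf labels.

    Built by attaching each leaf on a uniformly chosen edge (including the
    root edge) of the growing tree; leaf labels must follow the
    suffix-underscore naming convention.  Used for topology-level tests and
    benchmarks where no evolutionary model is needed.
    """
    if len(leaf_names) < 2:
        raise ValueError("need at least 2 leaves")
    rng = _rng(rng_seed)

    def leaf(name: str) -> TreeNode:
        node = TreeNode(name=name)
        node.seq_id, _, node.species = name.rpartition("_")
        return node

    root = leaf(leaf_names[0])
    for name in leaf_names[1:]:
        nodes = list(root.traverse())
        target = nodes[int(rng.integers(len(nodes)))]
        new = TreeNode()
        parent = target.parent
        new.add_child(target)
        new.add_child(leaf(name))
        if parent is None:
            root = new
        else:
            parent.children[parent.children.index(target)] = new
            new.parent = parent
    return GeneTree(root)


def true_orthologs(rec: SimRecord) -> set[frozenset[Gene]]:
    """Ground-truth ortholog pairs: leaf pairs whose LCA is a true speciation."""
    if rec.gene_tree is None:
        return set()
    root = rec.gene_tree.root
    out: set[frozenset[Gene]] = set()

    def walk(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf:
            return [node]
        child_leaves = [walk(c) for c in node.children]
        if node.true_event == "speciation":
            for la, lb in itertools.combinations(child_leaves, 2):
                for a in la:
                    for b in lb:
                        out.add(
                            frozenset(
                                (Gene(a.seq_id, a.species), Gene(b.seq_id, b.species))
                            )
                        )
        return [leaf for leaves in child_leaves for leaf in leaves]

    walk(root)
    return out


def true_paralogs(rec: SimRecord) -> set[frozenset[Gene]]:
    """Complement of :func:`true_orthologs` over all same-tree leaf pairs."""
    if rec.gene_tree is None:
        return set()
    genes = [Gene(l.seq_id, l.species) for l in rec.gene_tree.leaves()]
    all_pairs = {frozenset(p) for p in itertools.combinations(genes, 2)}
    return all_pairs - true_orthologs(rec)
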