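"""LCA reconciliation, duplication/loss counting and gene-tree parsimony.

Each gene-tree node is mapped to the last common ancestor (in the species
tree) of its descendant species.  A node is a duplication when its mapping
coincides with the mapping of at least one child.  Losses are counted per
gene-tree edge from the species-tree path length between the two mappings:
``d - 1`` below a speciation, ``d`` below a duplication, where ``d`` is the
number of species-tree edges between the mapped nodes.

Gene-tree parsimony scores a candidate species tree by the total
duplication (or duplication-plus-loss) cost over a gene-tree collection;
for small species sets all rooted binary topologies can be enumerated
exhaustively.
"""

from __future__ import annotations

from dataclasses import dataclass

from .treeio import (
    GeneTree,
    SpeciesTree,
    TreeError,
    TreeNode,
    parse_species_tree,
)

DUP = "dup"
DUP_PLUS_LOSS = "dup_plus_loss"


@dataclass
class Reconciliation:
    mapping: dict[int, TreeNode]
    events: dict[int, str]
    dup_count: int
    loss_count: int

    def cost(self, mode: str = DUP_PLUS_LOSS) -> int:
        if mode == DUP:
            return self.dup_count
        if mode == DUP_PLUS_LOSS:
            return self.dup_count + self.loss_count
        raise ValueError(f"unknown cost mode {mode!r}")


def _check_binary(root: TreeNode, what: str) -> None:
    for node in root.traverse():
        if node.children and len(node.children) != 2:
            raise TreeError(
                f"{what} is not binary (node with {len(node.children)} "
                "children); resolve multifurcations upstream"
            )


def lca_reconcile(gene_tree: GeneTree, species_tree: SpeciesTree) -> Reconciliation:
    """Reconcile a rooted binary gene tree against a rooted species tree."""
    _check_binary(gene_tree.root, "gene tree")
    _check_binary(species_tree.root, "species tree")
    species_tree.check_species(gene_tree.species_set)

    mapping: dict[int, TreeNode] = {}
    events: dict[int, str] = {}
    dup_count = 0
    loss_count = 0
    for node in gene_tree.root.postorder():
        if node.is_leaf:
            mapping[id(node)] = species_tree.leaf_map[node.species]
            continue
        child_maps = [mapping[id(c)] for c in node.children]
        m = species_tree.lca_nodes(child_maps[0], child_maps[1])
        mapping[id(node)] = m
        is_dup = any(cm is m for cm in child_maps)
        events[id(node)] = "duplication" if is_dup else "speciation"
        if is_dup:
            dup_count += 1
        for cm in child_maps:
            d = species_tree.depth(cm) - species_tree.depth(m)
            loss_count += d if is_dup else max(0, d - 1)
    return Reconciliation(mapping, events, dup_count, loss_count)


def score_species_tree(
    gene_trees: list[GeneTree],
    species_tree: SpeciesTree,
    cost: str = DUP_PLUS_LOSS,
) -> int:
    """Total reconciliation cost of a gene-tree collection (gene-tree parsimony)."""
    if not gene_trees:
        raise ValueError("empty gene-tree collection")
    total = 0
    for i, tree in enumerate(gene_trees):
        try:
            total += lca_reconcile(tree, species_tree).cost(cost)
        except TreeError as exc:
            raise TreeError(f"gene tree #{i} is not reconcilable: {exc}") from exc
    return total


# ---------------------------------------------------------------------------
# Exhaustive species-tree search (fast bitmask reconciliation inside)


@dataclass
class SearchResult:
    best: SpeciesTree
    cost: int
    co_optimal: list[str]  # newick strings of all minimum-cost topologies


def _tree_program(gene_tree: GeneTree, species_bit: dict[str, int]):
    """Flatten a binary gene tree into postorder merge instructions."""
    _check_binary(gene_tree.root, "gene tree")
    nodes = list(gene_tree.root.postorder())
    index = {id(n): i for i, n in enumerate(nodes)}
    program = []
    for n in nodes:
        if n.is_leaf:
            program.append((-1, species_bit[n.species]))
        else:
            program.append((index[id(n.children[0])], index[id(n.children[1])]))
    return program


class _SpeciesIndex:
    """Bitmask/depth tables for one candidate species topology."""

    def __init__(self, topo, species_bit: dict[str, int]):
        self.mask: list[int] = []
        self.depth: list[int] = []
        self.leaf_node: dict[int, int] = {}
        self.parent: list[int] = []
        self._build(topo, species_bit, -1, 0)
        self._memo: dict[int, int] = {}

    def _build(self, topo, species_bit, parent, depth) -> int:
        idx = len(self.mask)
        self.mask.append(0)
        self.depth.append(depth)
        self.parent.append(parent)
        if isinstance(topo, str):
            bit = species_bit[topo]
            self.mask[idx] = 1 << bit
            self.leaf_node[1 << bit] = idx
        else:
            m = 0
            for sub in topo:
                child = self._build(sub, species_bit, idx, depth + 1)
                m |= self.mask[child]
            self.mask[idx] = m
        return idx

    def resolve(self, mask: int) -> int:
        """Lowest node whose subtree mask contains ``mask``."""
        node = self._memo.get(mask)
        if node is not None:
            return node
        low = mask & -mask
        node = self.leaf_node[low]
        while mask & ~self.mask[node]:
            node = self.parent[node]
        self._memo[mask] = node
        return node


def _program_cost(program, index: _SpeciesIndex, dup_only: bool) -> int:
    masks = [0] * len(program)
    nodes = [0] * len(program)
    cost = 0
    for i, (a, b) in enumerate(program):
        if a < 0:
            masks[i] = 1 << b
            nodes[i] = index.leaf_node[1 << b]
            continue
        mask = masks[a] | masks[b]
        masks[i] = mask
        node = index.resolve(mask)
        nodes[i] = node
        is_dup = nodes[a] == node or nodes[b] == node
        if is_dup:
            cost += 1
        if not dup_only:
            for child in (a, b):
                d = index.depth[nodes[child]] - index.depth[node]
                cost += d if is_dup else max(0, d - 1)
    return cost


def enumerate_rooted_topologies(labels: list[str]):
    """Yield every rooted binary topology over ``labels`` as nested tuples."""

    def add_leaf(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            a, b = tree
            for na in add_leaf(a, leaf):
                yield (na, b)
            for nb in add_leaf(b, leaf):
                yield (a, nb)

    def gen(items):
        if len(items) == 1:
            yield items[0]
            return
        for sub in gen(items[:-1]):
            yield from add_leaf(sub, items[-1])

    yield from gen(list(labels))


def _topo_newick(topo) -> str:
    if isinstance(topo, str):
        return topo
    return "(" + ",".join(_topo_newick(t) for t in topo) + ")"


def search_species_trees(
    gene_trees: list[GeneTree],
    species: set[str] | list[str],
    cost: str = DUP_PLUS_LOSS,
) -> SearchResult:
    """Exhaustive gene-tree-parsimony search over all rooted binary species trees.

    Restricted to at most 8 species — (2n-3)!! topologies are enumerated.
    Returns the minimum-cost tree (ties broken by lexicographically smallest
    Newick string) together with all co-optimal topologies.
    """
    species = sorted(set(species))
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    if len(species) > 8:
        raise ValueError(
            "exhaustive search is limited to 8 species; use an external "
            "heuristic search (SPR/NNI) for larger sets"
        )
    if not gene_trees:
        raise ValueError("empty gene-tree collection")
    for tree in gene_trees:
        extra = tree.species_set - set(species)
        if extra:
            raise TreeError(
                f"gene tree contains species outside the search set: {sorted(extra)}"
            )
    species_bit = {sp: i for i, sp in enumerate(species)}
    programs = [_tree_program(t, species_bit) for t in gene_trees]
    dup_only = cost == DUP

    best_cost = None
    co_optimal: list[str] = []
    for topo in enumerate_rooted_topologies(species):
        index = _SpeciesIndex(topo, species_bit)
        total = sum(_program_cost(p, index, dup_only) for p in programs)
        if best_cost is None or total < best_cost:
            best_cost = total
            co_optimal = [_topo_newick(topo) + ";"]
        elif total == best_cost:
            co_optimal.append(_topo_newick(topo) + ";")
    co_optimal.sort()
    return SearchResult(
        best=parse_species_tree(co_optimal[0]),
        cost=best_cost,
        co_optimal=co_optimal,
    )
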