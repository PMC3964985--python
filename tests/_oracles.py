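"""Independent brute-force reference implementations used only by tests.

Each oracle is written the dumbest defensible way — explicit enumeration,
quadratic scans — and never shares code paths with the package internals it
checks.
"""

from __future__ import annotations

import itertools

from phylomekit.treeio import Alignment, GeneTree, SpeciesTree, TreeNode


# ---------------------------------------------------------------------------
# Robinson–Foulds by explicit per-edge split enumeration


def brute_force_splits(root: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Every non-trivial unrooted split as an unordered pair of leaf-name sets."""
    all_leaves = frozenset(l.name for l in root.leaves())
    splits = set()
    for node in root.traverse():
        if node.parent is None or node.is_leaf:
            continue
        below = frozenset(l.name for l in node.leaves())
        above = all_leaves - below
        if len(below) >= 2 and len(above) >= 2:
            splits.add(frozenset((below, above)))
    return splits


def brute_force_rf(t1: GeneTree, t2: GeneTree) -> tuple[int, float]:
    s1 = brute_force_splits(t1.root)
    s2 = brute_force_splits(t2.root)
    raw = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    return raw, (raw / denom if denom else 0.0)


# ---------------------------------------------------------------------------
# Naive quadratic LCA reconciliation


def naive_reconcile(gene_tree: GeneTree, species_tree: SpeciesTree):
    """(dup_count, loss_count) by scanning all species nodes per gene node."""
    sp_nodes = list(species_tree.root.traverse())
    leafsets = {id(n): frozenset(l.name for l in n.leaves()) for n in sp_nodes}

    def map_node(species: frozenset[str]) -> TreeNode:
        best = None
        for node in sp_nodes:
            if species <= leafsets[id(node)]:
                if best is None or len(leafsets[id(node)]) < len(leafsets[id(best)]):
                    best = node
        return best

    def edge_distance(anc: TreeNode, desc: TreeNode) -> int:
        d = 0
        node = desc
        while node is not anc:
            node = node.parent
            d += 1
        return d

    dup = loss = 0
    for node in gene_tree.root.traverse():
        if node.is_leaf:
            continue
        m = map_node(node.species_set())
        child_maps = [map_node(c.species_set()) for c in node.children]
        is_dup = any(cm is m for cm in child_maps)
        if is_dup:
            dup += 1
        for cm in child_maps:
            d = edge_distance(m, cm)
            loss += d if is_dup else max(0, d - 1)
    return dup, loss


# ---------------------------------------------------------------------------
# Orthology by direct LCA lookup on leaf ancestor chains


def naive_lca(a: TreeNode, b: TreeNode) -> TreeNode:
    anc_a = [a] + a.ancestors()
    ids = {id(n) for n in anc_a}
    node = b
    while id(node) not in ids:
        node = node.parent
    return node


def naive_ortholog_pairs(tree: GeneTree) -> set[frozenset[tuple[str, str]]]:
    """All ortholog pairs: distinct species and a speciation at the LCA."""
    pairs = set()
    for a, b in itertools.combinations(tree.leaves(), 2):
        if a.species == b.species:
            continue
        if naive_lca(a, b).event == "speciation":
            pairs.add(frozenset(((a.seq_id, a.species), (b.seq_id, b.species))))
    return pairs


def naive_nodal_distance(a: TreeNode, b: TreeNode) -> int:
    if a is b:
        return 0
    lca = naive_lca(a, b)
    d = 0
    for start in (a, b):
        node = start
        while node is not lca:
            node = node.parent
            d += 1
    return d


# ---------------------------------------------------------------------------
# Alignment column filtering by a global residue-pair table


def pair_table(alignments: list[Alignment]) -> dict[tuple, int]:
    """Count, over all alignments, how often each residue pair shares a column."""
    table: dict[tuple, int] = {}
    for aln in alignments:
        pos = {seq_id: 0 for seq_id in aln.ids}
        cols: list[list[tuple[str, int]]] = [[] for _ in range(aln.ncol)]
        for r, seq_id in enumerate(aln.ids):
            p = 0
            for c, ch in enumerate(aln.seqs[r]):
                if ch != "-":
                    cols[c].append((seq_id, p))
                    p += 1
        for col in cols:
            for (ia, pa), (ib, pb) in itertools.combinations(sorted(col), 2):
                table[(ia, pa, ib, pb)] = table.get((ia, pa, ib, pb), 0) + 1
    return table


def brute_force_kept_columns(
    consensus: Alignment,
    alternatives: list[Alignment],
    mode: str,
    min_fraction: float = 0.5,
) -> list[int]:
    """Re-derive the kept-column list from a flat pair-count table."""
    table = pair_table(alternatives)
    K = len(alternatives)
    kept = []
    for c in range(consensus.ncol):
        residues = []
        for r, seq_id in enumerate(consensus.ids):
            idx = consensus.residue_index(r)[c]
            if idx is not None:
                residues.append((seq_id, idx))
        pairs = [
            tuple(x for pair in sorted([p, q]) for x in pair)
            for p, q in itertools.combinations(sorted(residues), 2)
        ]
        supports = [table.get(p, 0) for p in pairs]
        if mode == "strict":
            keep = all(s >= 2 for s in supports)
        else:
            mean = sum(supports) / (len(supports) * K) if supports else 1.0
            keep = mean >= min_fraction
        if keep:
            kept.append(c)
    return kept
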