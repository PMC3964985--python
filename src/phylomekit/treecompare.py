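"""Tree and orthology-set comparison: Robinson–Foulds distance and
ortholog-pair conservation between releases.

The RF distance counts bipartitions present in exactly one of the two
trees; the normalized value divides by the total number of non-trivial
bipartitions in both (which equals ``2(n-3)`` for two binary trees on the
same ``n`` leaves).  A ``prune_to_shared`` mode first restricts both trees
to their common leaves — proteome updates change leaf sets, so comparing
tree versions requires it.
"""

from __future__ import annotations

from .treeio import GeneTree, SpeciesTree, TreeError, TreeNode, prune_to


def _leaf_key(leaf: TreeNode) -> str:
    return leaf.name if leaf.name is not None else f"{leaf.seq_id}_{leaf.species}"


def bipartitions(root: TreeNode) -> tuple[frozenset[str], set[frozenset[str]]]:
    """Non-trivial unrooted bipartitions of a tree, in canonical form.

    Each split is stored as its lexicographically smaller side (comparing
    the sorted leaf-name tuples), so complementary representations coincide.
    """
    universe = frozenset(_leaf_key(leaf) for leaf in root.leaves())
    parts: set[frozenset[str]] = set()
    for node in root.traverse():
        if node.parent is None or node.is_leaf:
            continue
        side = frozenset(_leaf_key(leaf) for leaf in node.leaves())
        if len(side) <= 1 or len(side) >= len(universe) - 1:
            continue
        parts.add(_canonical(side, universe))
    return universe, parts


def _canonical(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    return side if tuple(sorted(side)) < tuple(sorted(other)) else other


def rf_distance(
    t1: GeneTree | SpeciesTree,
    t2: GeneTree | SpeciesTree,
    mode: str = "strict",
) -> tuple[int, float, int]:
    """Robinson–Foulds distance between two trees.

    Returns ``(raw, normalized, n_shared_leaves)``.  ``strict`` requires
    identical leaf sets; ``prune_to_shared`` restricts both trees to their
    common leaves first (at least 4 required).
    """
    r1, r2 = t1.root, t2.root
    l1 = {_leaf_key(leaf) for leaf in r1.leaves()}
    l2 = {_leaf_key(leaf) for leaf in r2.leaves()}
    if mode == "strict":
        if l1 != l2:
            raise TreeError(
                "leaf sets differ; use mode='prune_to_shared' to compare "
                "on the common leaves"
            )
        shared = l1
    elif mode == "prune_to_shared":
        shared = l1 & l2
        if len(shared) < 4:
            raise TreeError(
                f"only {len(shared)} shared leaves; need at least 4"
            )
        r1 = prune_to(r1, lambda leaf: _leaf_key(leaf) in shared)
        r2 = prune_to(r2, lambda leaf: _leaf_key(leaf) in shared)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    _, p1 = bipartitions(r1)
    _, p2 = bipartitions(r2)
    raw = len(p1 ^ p2)
    denom = len(p1) + len(p2)
    normalized = raw / denom if denom else 0.0
    return raw, normalized, len(shared)


def ortholog_conservation(
    calls_v1,
    calls_v2,
    denominator: str = "v1",
) -> float:
    """Fraction of ortholog pairs conserved between two prediction sets.

    Inputs are iterables of unordered gene pairs (any 2-element collections;
    they are normalized to frozensets).  ``denominator`` selects the
    reference set: the first release (``v1``) or the ``union`` of both.
    Cross-release identifier mapping is the caller's responsibility.
    """
    v1 = {frozenset(p) for p in calls_v1}
    v2 = {frozenset(p) for p in calls_v2}
    if denominator == "v1":
        denom = v1
    elif denominator == "union":
        denom = v1 | v2
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if not denom:
        raise ValueError("empty denominator set")
    return len(v1 & v2) / len(denom)
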