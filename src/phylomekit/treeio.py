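"""Tree and alignment data model with Newick/NHX and FASTA readers/writers.

Gene trees follow the PhylomeDB leaf-naming convention: an opaque sequence
identifier joined to an uppercase species mnemonic (UniProt style), e.g.
``Phy00086SJ_HUMAN``.  Species trees are plain Newick trees whose leaves are
species mnemonics and whose internal labels, when non-numeric, name taxonomic
clades (e.g. ``Primates``).

Internal-node annotations travel as NHX tags:

========  =====================================
tag       meaning
========  =====================================
``Ev``    event, ``D`` (duplication) / ``S`` (speciation)
``S``     species mnemonic (overrides the leaf-name split)
``sos``   species-overlap score in [0, 1]
``age``   phylostratigraphic relative-age index
``B``     branch support
========  =====================================
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

from Bio import SeqIO

GAP = "-"

SPECIATION = "speciation"
DUPLICATION = "duplication"

_NHX_EVENT_IN = {"S": SPECIATION, "D": DUPLICATION}
_NHX_EVENT_OUT = {SPECIATION: "S", DUPLICATION: "D"}


class TreeError(Exception):
    """Base class for tree model errors."""


class NewickParseError(TreeError):
    """Malformed Newick input; carries the 0-based offset of the problem."""

    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} (at offset {pos})")
        self.pos = pos


class LeafNamingError(TreeError):
    """A leaf label does not follow the configured naming convention."""


class TreeNode:
    """A rooted (possibly multifurcating) tree node.

    One class serves both gene trees and species trees; gene leaves carry
    ``seq_id``/``species``, species-tree nodes only use ``name``.
    """

    __slots__ = (
        "name",
        "children",
        "parent",
        "branch_length",
        "support",
        "event",
        "overlap_score",
        "age_index",
        "seq_id",
        "species",
        "true_event",
    )

    def __init__(self, name: str | None = None, branch_length: float | None = None):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.branch_length = branch_length
        self.support: float | None = None
        self.event: str | None = None
        self.overlap_score: float | None = None
        self.age_index: int | None = None
        self.seq_id: str | None = None
        self.species: str | None = None
        self.true_event: str | None = None

    # -- structure ---------------------------------------------------------

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def traverse(self) -> Iterator["TreeNode"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.traverse() if n.is_leaf]

    def ancestors(self) -> list["TreeNode"]:
        """Parent chain from this node (exclusive) up to the root (inclusive)."""
        out = []
        node = self.parent
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    def species_set(self) -> frozenset[str]:
        """Set of species mnemonics over the leaves below this node."""
        return frozenset(
            (leaf.species if leaf.species is not None else leaf.name)
            for leaf in self.leaves()
        )

    def copy(self) -> "TreeNode":
        new = TreeNode(self.name, self.branch_length)
        new.support = self.support
        new.event = self.event
        new.overlap_score = self.overlap_score
        new.age_index = self.age_index
        new.seq_id = self.seq_id
        new.species = self.species
        new.true_event = self.true_event
        for child in self.children:
            new.add_child(child.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.name or ''} nleaves={len(self.leaves())}>"


# ---------------------------------------------------------------------------
# Leaf naming conventions


def parse_leaf_name(
    raw: str,
    convention: str = "suffix_underscore",
    regex: str | None = None,
) -> tuple[str, str]:
    """Split a leaf label into ``(seq_id, species)``.

    ``suffix_underscore``: species is the token after the LAST underscore
    (``Phy00086SJ_HUMAN`` -> ``("Phy00086SJ", "HUMAN")``).
    ``prefix_underscore``: species is the token before the FIRST underscore.
    ``regex``: ``regex`` must contain named groups ``seq_id`` and ``species``.
    """
    if not raw:
        raise LeafNamingError("empty leaf name")
    if convention == "suffix_underscore":
        seq_id, sep, species = raw.rpartition("_")
        if not sep or not seq_id or not species:
            raise LeafNamingError(
                f"leaf name {raw!r} has no '_species' suffix "
                "(expected e.g. 'Phy00086SJ_HUMAN')"
            )
        return seq_id, species
    if convention == "prefix_underscore":
        species, sep, seq_id = raw.partition("_")
        if not sep or not seq_id or not species:
            raise LeafNamingError(f"leaf name {raw!r} has no 'species_' prefix")
        return seq_id, species
    if convention == "regex":
        if regex is None:
            raise ValueError("convention 'regex' requires a pattern")
        m = re.fullmatch(regex, raw)
        if m is None:
            raise LeafNamingError(f"leaf name {raw!r} does not match {regex!r}")
        try:
            return m.group("seq_id"), m.group("species")
        except IndexError as exc:
            raise ValueError(
                "regex convention needs named groups 'seq_id' and 'species'"
            ) from exc
    raise ValueError(f"unknown naming convention {convention!r}")


# ---------------------------------------------------------------------------
# Newick / NHX parsing

_LABEL_RE = re.compile(r"[^,();:\[\]]+")
_NUMBER_RE = re.compile(r"[-+]?\d+(\.\d*)?([eE][-+]?\d+)?")


def _parse_nhx(comment: str) -> dict[str, str]:
    body = comment[len("&&NHX:"):] if comment.startswith("&&NHX:") else ""
    tags: dict[str, str] = {}
    for item in body.split(":"):
        if not item:
            continue
        key, _, value = item.partition("=")
        tags[key] = value
    return tags


def _parse_newick_topology(text: str) -> TreeNode:
    """Recursive-descent Newick parser keeping NHX comments as node tags."""
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and text[pos].isspace():
            pos += 1

    def parse_clade() -> TreeNode:
        nonlocal pos
        skip_ws()
        node = TreeNode()
        if pos < n and text[pos] == "(":
            pos += 1
            while True:
                node.add_child(parse_clade())
                skip_ws()
                if pos >= n:
                    raise NewickParseError("unbalanced parentheses", pos)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError(
                    f"expected ',' or ')', found {text[pos]!r}", pos
                )
        # label
        skip_ws()
        m = _LABEL_RE.match(text, pos)
        if m:
            node.name = m.group().strip()
            pos = m.end()
        # branch length
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            skip_ws()
            m = _NUMBER_RE.match(text, pos)
            if not m:
                raise NewickParseError("expected branch length after ':'", pos)
            node.branch_length = float(m.group())
            pos = m.end()
        # NHX comment
        skip_ws()
        if pos < n and text[pos] == "[":
            end = text.find("]", pos)
            if end < 0:
                raise NewickParseError("unterminated comment", pos)
            comment = text[pos + 1:end]
            pos = end + 1
            for key, value in _parse_nhx(comment).items():
                _apply_nhx_tag(node, key, value)
        if node.is_leaf and node.name is None and node.branch_length is None:
            raise NewickParseError("empty clade", pos)
        return node

    root = parse_clade()
    skip_ws()
    if pos >= n or text[pos] != ";":
        raise NewickParseError("expected terminating ';'", pos)
    pos += 1
    skip_ws()
    if pos != n:
        raise NewickParseError("trailing characters after ';'", pos)
    return root


def _apply_nhx_tag(node: TreeNode, key: str, value: str) -> None:
    if key == "Ev" and value in _NHX_EVENT_IN:
        node.event = _NHX_EVENT_IN[value]
    elif key == "S":
        node.species = value
    elif key == "sos":
        node.overlap_score = float(value)
    elif key == "age":
        node.age_index = int(value)
    elif key == "B":
        node.support = float(value)
    # unknown tags are ignored


def _is_number(token: str) -> bool:
    m = _NUMBER_RE.fullmatch(token)
    return m is not None


# ---------------------------------------------------------------------------
# Trees


class GeneTree:
    """A rooted gene tree whose leaves carry ``(seq_id, species)``."""

    def __init__(self, root: TreeNode, naming: str = "suffix_underscore"):
        self.root = root
        self.naming = naming
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for leaf in self.root.leaves():
            if not leaf.species:
                raise TreeError(f"leaf {leaf.name!r} has no species assigned")
            key = (leaf.seq_id or leaf.name, leaf.species)
            if key in seen:
                raise TreeError(f"duplicate (seq_id, species) pair {key!r}")
            seen.add(key)

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def find_leaf(self, ref) -> TreeNode:
        """Resolve a leaf by node, raw name, seq_id or ``(seq_id, species)``."""
        if isinstance(ref, TreeNode):
            return ref
        for leaf in self.root.leaves():
            if ref == leaf.name or ref == leaf.seq_id:
                return leaf
            if isinstance(ref, tuple) and tuple(ref) == (leaf.seq_id, leaf.species):
                return leaf
        raise TreeError(f"leaf {ref!r} not found in tree")

    @property
    def species_set(self) -> frozenset[str]:
        return self.root.species_set()

    def copy(self) -> "GeneTree":
        return GeneTree(self.root.copy(), naming=self.naming)

    def is_labeled(self) -> bool:
        return all(
            n.event in (SPECIATION, DUPLICATION)
            for n in self.root.traverse()
            if not n.is_leaf
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneTree):
            return NotImplemented
        return _topology_key(self.root) == _topology_key(other.root)

    def __hash__(self):  # pragma: no cover - identity hashing suffices
        return id(self)


class SpeciesTree:
    """A rooted reference species tree / taxonomy.

    Leaves are species mnemonics; internal nodes optionally carry clade names
    (taxonomic levels).  Provides LCA queries used by reconciliation,
    seed-relative rooting and phylostratigraphy.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.leaf_map: dict[str, TreeNode] = {}
        for leaf in root.leaves():
            if leaf.name in self.leaf_map:
                raise TreeError(f"duplicate species mnemonic {leaf.name!r}")
            self.leaf_map[leaf.name] = leaf
        self._depth: dict[int, int] = {}
        for node in root.traverse():
            self._depth[id(node)] = (
                0 if node.parent is None else self._depth[id(node.parent)] + 1
            )

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.leaf_map)

    def depth(self, node: TreeNode) -> int:
        return self._depth[id(node)]

    def check_species(self, species: Iterable[str]) -> None:
        missing = sorted(set(species) - set(self.leaf_map))
        if missing:
            raise TreeError(
                f"species not present in the species tree: {', '.join(missing)}"
            )

    def lca(self, species: Iterable[str]) -> TreeNode:
        """Last common ancestor of a set of species mnemonics."""
        species = list(species)
        self.check_species(species)
        nodes = [self.leaf_map[s] for s in species]
        if not nodes:
            raise TreeError("lca of an empty species set")
        current = nodes[0]
        chain = {id(current)}
        walker = current
        while walker.parent is not None:
            walker = walker.parent
            chain.add(id(walker))
        lca = current
        for node in nodes[1:]:
            walker = node
            while id(walker) not in chain:
                walker = walker.parent
            if self._depth[id(walker)] < self._depth[id(lca)]:
                lca = walker
        return lca

    def lca_nodes(self, a: TreeNode, b: TreeNode) -> TreeNode:
        da, db = self._depth[id(a)], self._depth[id(b)]
        while da > db:
            a = a.parent
            da -= 1
        while db > da:
            b = b.parent
            db -= 1
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def copy(self) -> "SpeciesTree":
        return SpeciesTree(self.root.copy())


def _topology_key(node: TreeNode):
    # tag leaves/internals so mixed children sort without type errors
    if node.is_leaf:
        return ("L", node.name)
    return ("I", tuple(sorted(_topology_key(c) for c in node.children)))


# ---------------------------------------------------------------------------
# Public parse / write API


def parse_newick(
    text: str,
    naming: str = "suffix_underscore",
    regex: str | None = None,
) -> GeneTree:
    """Parse a Newick/NHX string into a :class:`GeneTree`.

    Leaf names are split into ``(seq_id, species)`` under ``naming`` (an NHX
    ``S`` tag on a leaf overrides the split).  Numeric internal labels are
    read as branch support.  Multifurcations are preserved.
    """
    root = _parse_newick_topology(text)
    for node in root.traverse():
        if node.is_leaf:
            if node.name is None:
                raise LeafNamingError("unnamed leaf in gene tree")
            seq_id, species = parse_leaf_name(node.name, naming, regex)
            node.seq_id = seq_id
            if node.species is None:  # NHX S tag wins when present
                node.species = species
        elif node.name is not None and _is_number(node.name):
            node.support = float(node.name)
            node.name = None
    return GeneTree(root, naming=naming)


def parse_species_tree(text: str) -> SpeciesTree:
    """Parse a Newick species tree; non-numeric internal labels name clades."""
    root = _parse_newick_topology(text)
    for node in root.traverse():
        if not node.is_leaf and node.name is not None and _is_number(node.name):
            node.support = float(node.name)
            node.name = None
    return SpeciesTree(root)


def _format_length(value: float) -> str:
    text = f"{value:.6f}".rstrip("0").rstrip(".")
    return text if text else "0"


def _node_to_newick(node: TreeNode, annotated: bool, parts: list[str]) -> None:
    if node.children:
        parts.append("(")
        for i, child in enumerate(node.children):
            if i:
                parts.append(",")
            _node_to_newick(child, annotated, parts)
        parts.append(")")
        if node.name is not None:
            parts.append(node.name)
        elif node.support is not None and not annotated:
            parts.append(_format_length(node.support))
    else:
        parts.append(node.name or "")
    if node.branch_length is not None:
        parts.append(f":{_format_length(node.branch_length)}")
    if annotated:
        tags = []
        if node.event in _NHX_EVENT_OUT:
            tags.append(f"Ev={_NHX_EVENT_OUT[node.event]}")
        if node.overlap_score is not None:
            tags.append(f"sos={node.overlap_score:.6g}")
        if node.age_index is not None:
            tags.append(f"age={node.age_index}")
        if node.support is not None:
            tags.append(f"B={_format_length(node.support)}")
        if node.is_leaf and node.species is not None:
            tags.append(f"S={node.species}")
        if tags:
            parts.append("[&&NHX:" + ":".join(tags) + "]")


def write_newick(tree: GeneTree | SpeciesTree | TreeNode, annotated: bool = False) -> str:
    """Serialize a tree to Newick (NHX tags when ``annotated`` is true)."""
    root = tree if isinstance(tree, TreeNode) else tree.root
    parts: list[str] = []
    _node_to_newick(root, annotated, parts)
    parts.append(";")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Rerooting / pruning primitives


def reroot_on_edge(
    root: TreeNode,
    outgroup: TreeNode,
    outgroup_fraction: float = 0.5,
) -> TreeNode:
    """Reroot so that ``outgroup`` becomes one child of a fresh binary root.

    The edge above ``outgroup`` is split; ``outgroup`` keeps
    ``outgroup_fraction`` of its length.  The old root is suppressed if it
    becomes unary.  Nodes are re-used, not copied.
    """
    if outgroup is root:
        raise TreeError("cannot reroot on the root itself")
    if outgroup.parent is root and len(root.children) == 2:
        # already rooted on this edge: just relocate the root along it
        sibling = next(c for c in root.children if c is not outgroup)
        if outgroup.branch_length is not None:
            total = outgroup.branch_length
            outgroup.branch_length = total * outgroup_fraction
            if sibling.branch_length is not None:
                sibling.branch_length += total - outgroup.branch_length
        return root
    chain = [outgroup]
    node = outgroup.parent
    while node is not None:
        chain.append(node)
        node = node.parent

    new_root = TreeNode()
    if outgroup.branch_length is not None:
        total = outgroup.branch_length
        outgroup.branch_length = total * outgroup_fraction
        carry: float | None = total - outgroup.branch_length
    else:
        carry = None
    new_root.add_child(outgroup)

    prev = new_root
    prev_bl = carry
    for i in range(1, len(chain)):
        node = chain[i]
        on_path = chain[i - 1]
        node.children = [c for c in node.children if c is not on_path]
        next_bl = node.branch_length
        node.branch_length = prev_bl
        node.parent = None
        prev.add_child(node)
        prev, prev_bl = node, next_bl
    _suppress_unary(new_root)
    return new_root


def _suppress_unary(root: TreeNode) -> None:
    # root retains >= 2 children at every call site; only inner nodes shrink
    for node in list(root.traverse()):
        while len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            if child.branch_length is not None or node.branch_length is not None:
                child.branch_length = (child.branch_length or 0.0) + (
                    node.branch_length or 0.0
                )
            idx = node.parent.children.index(node)
            node.parent.children[idx] = child
            child.parent = node.parent
            node = child


def prune_to(root: TreeNode, keep: Callable[[TreeNode], bool]) -> TreeNode | None:
    """Remove leaves failing ``keep``; suppress resulting unary nodes.

    Returns the new root, or ``None`` if nothing is kept.  Operates on a copy.
    """
    root = root.copy()

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return node if keep(node) else None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if child.branch_length is not None or node.branch_length is not None:
                child.branch_length = (child.branch_length or 0.0) + (
                    node.branch_length or 0.0
                )
            return child
        node.children = []
        for c in kept:
            node.add_child(c)
        return node

    new_root = rec(root)
    if new_root is not None:
        new_root.parent = None
    return new_root


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class Alignment:
    """An ordered gapped protein alignment (gap character ``-``).

    ``rows`` maps 1:1 onto ``ids``/``seqs``; all gapped strings share the
    same column count.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def ncol(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    @property
    def nrow(self) -> int:
        return len(self.ids)

    def ungapped(self, row: int) -> str:
        return self.seqs[row].replace(GAP, "")

    def residue_index(self, row: int) -> list[int | None]:
        """Per-column 0-based ungapped residue position (None at gaps)."""
        out: list[int | None] = []
        pos = 0
        for ch in self.seqs[row]:
            if ch == GAP:
                out.append(None)
            else:
                out.append(pos)
                pos += 1
        return out

    def select_columns(self, columns: Sequence[int]) -> "Alignment":
        seqs = ["".join(s[c] for c in columns) for s in self.seqs]
        return Alignment(list(self.ids), seqs)

    @classmethod
    def from_fasta(cls, path_or_handle) -> "Alignment":
        ids, seqs = [], []
        for record in SeqIO.parse(path_or_handle, "fasta"):
            ids.append(record.id)
            seqs.append(str(record.seq))
        return cls(ids, seqs)

    def to_fasta(self, handle) -> None:
        for name, seq in zip(self.ids, self.seqs):
            handle.write(f">{name}\n{seq}\n")
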