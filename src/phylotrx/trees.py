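"""Phylogenetic tree data model, Newick I/O, bipartitions, and the
topological distance d_T.

The distance implemented here is the Robinson-Foulds symmetric-difference
count over non-trivial bipartitions (splits) of the unrooted topology:
``d_T = |splits(A) Δ splits(B)|``.  For two fully resolved binary trees this
equals twice the number of splits present in one tree but not the other, so
``d_T`` is even and bounded by ``2(n - 3)`` for ``n`` shared taxa.  Branch
lengths never enter the distance.

Trees on different taxon sets are restricted to their common taxa before
comparison, so a tree missing a few species can be scored against a larger
reference directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Optional

__all__ = [
    "Taxon",
    "Node",
    "PhyloTree",
    "Bipartition",
    "NewickError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "robinson_foulds",
    "rf_from_splits",
    "restrict_to_taxa",
]


@dataclass(frozen=True)
class Taxon:
    """A tree tip: a species, optionally tagged with the tissue its
    transcriptome came from."""

    species_id: str
    tissue_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Node:
    """One node of a rooted tree representation.

    ``length`` is the length of the edge above this node; ``None`` means the
    length was never set (distinct from an explicit 0.0).
    """

    __slots__ = ("label", "length", "children")

    def __init__(self, label: Optional[str] = None,
                 length: Optional[float] = None,
                 children: Optional[list["Node"]] = None):
        self.label = label
        self.length = length
        self.children: list[Node] = children if children is not None else []

    @property
    def is_tip(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        return Node(self.label, self.length, [c.copy() for c in self.children])

    def walk(self) -> Iterator["Node"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))


class PhyloTree:
    """A labelled phylogenetic tree.

    Internally stored rooted (every tree read from Newick has a root node);
    topology statistics treat the tree as unrooted.  Tip labels must be
    unique.  Branch lengths, when set, are non-negative and in expected
    substitutions per site.
    """

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        labels = self.tip_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in self.root.walk():
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length on {node.label!r}")

    # -- basic queries -----------------------------------------------------

    def tips(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def taxa(self) -> frozenset[str]:
        return frozenset(self.tip_labels())

    def n_tips(self) -> int:
        return len(self.tips())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({write_newick(self)})"


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split of the taxon set induced by one internal edge
    of the unrooted tree.

    Canonical orientation: ``side_a`` holds the lexicographically smallest
    taxon, which makes the object hashable and order-independent.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    @staticmethod
    def make(part: frozenset[str], full: frozenset[str]) -> "Bipartition":
        other = full - part
        if not part or not other:
            raise ValueError("bipartition sides must both be non-empty")
        if min(part) < min(other):
            return Bipartition(part, other)
        return Bipartition(other, part)

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

_LABEL_FORBIDDEN = set("(),:;[]' \t\n")


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are optional and preserved exactly; absent lengths stay
    unset rather than defaulting to 0.  Duplicate tip labels are rejected.
    Malformed input raises :class:`NewickError` naming the character offset.
    """
    s = text.strip()
    if s.endswith(";"):
        s = s[:-1]
    if not s:
        raise NewickError("empty Newick string", 0)

    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_clade() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            open_at = pos
            pos += 1
            while True:
                node.children.append(parse_clade())
                if pos >= len(s):
                    pos = open_at
                    raise error("unbalanced '(' never closed")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            if len(node.children) < 2:
                raise error("internal node with fewer than 2 children")
        # label (tip name or internal support label)
        start = pos
        while pos < len(s) and s[pos] not in _LABEL_FORBIDDEN:
            pos += 1
        if pos > start:
            node.label = s[start:pos]
        if node.is_tip and node.label is None:
            raise error("tip without a label")
        # branch length
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and (s[pos].isdigit() or s[pos] in ".eE+-"):
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                pos = start
                raise error("invalid branch length")
        return node

    root = parse_clade()
    if pos != len(s):
        raise NewickError(f"trailing characters {s[pos:]!r}", pos)
    return PhyloTree(root)


def _min_descendant(node: Node) -> str:
    if node.is_tip:
        return node.label
    return min(_min_descendant(c) for c in node.children)


def write_newick(tree: PhyloTree, internal_labels: bool = True) -> str:
    """Serialize deterministically: children ordered by their smallest
    descendant tip label; branch lengths printed only when set, at full
    (round-trip) precision."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            out = node.label
        else:
            kids = sorted(node.children, key=_min_descendant)
            out = "(" + ",".join(fmt(c) for c in kids) + ")"
            if internal_labels and node.label is not None:
                out += str(node.label)
        if node.length is not None:
            out += f":{float(node.length)!r}"
        return out

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Bipartitions and the topological distance
# ---------------------------------------------------------------------------

def bipartitions(tree: PhyloTree) -> frozenset[Bipartition]:
    """All non-trivial splits of the unrooted topology.

    Rooted trees are implicitly unrooted: the two edges meeting at a
    bifurcating root induce the same split and are counted once.  A fully
    resolved binary tree on n >= 4 tips yields exactly n - 3 splits;
    multifurcations simply contribute fewer.
    """
    full = tree.taxa()
    if len(full) < 4:
        return frozenset()
    splits: set[Bipartition] = set()

    def below(node: Node) -> frozenset[str]:
        if node.is_tip:
            return frozenset((node.label,))
        got = frozenset().union(*(below(c) for c in node.children))
        if node is not tree.root:
            bp = Bipartition.make(got, full)
            if not bp.is_trivial:
                splits.add(bp)
        return got

    below(tree.root)
    return frozenset(splits)


def rf_from_splits(splits_a: frozenset[Bipartition],
                   splits_b: frozenset[Bipartition]) -> int:
    """Symmetric-difference count between two split sets."""
    return len(splits_a ^ splits_b)


def restrict_to_taxa(tree: PhyloTree, keep: frozenset[str]) -> PhyloTree:
    """Prune the tree down to ``keep``, suppressing the degree-2 nodes the
    pruning creates (their edge lengths are summed where set)."""

    def prune(node: Node) -> Optional[Node]:
        if node.is_tip:
            return node if node.label in keep else None
        kids = [k for k in (prune(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            return child
        node.children = kids
        return node

    root = prune(tree.root.copy())
    if root is None:
        raise ValueError("restriction removed every tip")
    if not root.is_tip and len(root.children) == 1:
        root = root.children[0]
        root.length = None
    return PhyloTree(root, tree.rooted)


def robinson_foulds(tree_a: PhyloTree, tree_b: PhyloTree) -> int:
    """Topological distance d_T between two trees.

    Trees with different taxon sets are first restricted to their common
    taxa.  Fewer than 4 common taxa leaves no informative split; the
    distance is then 0 and a warning is emitted.
    """
    common = tree_a.taxa() & tree_b.taxa()
    if not common:
        raise ValueError("trees share no taxa")
    if len(common) < 4:
        warnings.warn(
            f"only {len(common)} common taxa: no informative splits, d_T = 0",
            stacklevel=2,
        )
        return 0
    a = tree_a if tree_a.taxa() == common else restrict_to_taxa(tree_a, common)
    b = tree_b if tree_b.taxa() == common else restrict_to_taxa(tree_b, common)
    return rf_from_splits(bipartitions(a), bipartitions(b))
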