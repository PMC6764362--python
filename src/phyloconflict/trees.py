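"""Tree data model, newick I/O, ranked rooting, bipartitions, RF distances.

Trees are held in a lightweight mutable node structure.  Newick text is
parsed through dendropy and converted; writing is direct.  Bootstrap
supports ride in the internal-node label position and are treated as a
property of the edge below the node, so re-rooting preserves the
edge/support association.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "PhyloTree",
    "Bipartition",
    "TreeStats",
    "parse_newick",
    "root_ranked",
    "extract_bipartitions",
    "rf_distance",
    "tree_stats",
]


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


class Node:
    """A single tree node: leaf (label set) or internal (children set)."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None):
        self.label: Optional[str] = label
        self.length: Optional[float] = length
        self.support: Optional[float] = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or 'internal'}>"


class PhyloTree:
    """Rooted or unrooted labeled tree with optional lengths and supports.

    The structure is always stored parent->child from ``root``; the
    ``rooted`` flag records whether the root is meaningful.  An unrooted
    tree is conventionally stored with a basal multifurcation.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        self._validate()

    # ------------------------------------------------------------------
    # construction / validation
    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeError("leaf with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate leaf label: {node.label!r}")
                seen.add(node.label)
            if node.length is not None:
                if not math.isfinite(node.length) or node.length < 0:
                    raise TreeError(
                        f"invalid branch length {node.length!r} on {node.label or 'internal node'}"
                    )
            if node.support is not None:
                if node.is_leaf:
                    raise TreeError("support attached to a leaf")
                if not (0 <= node.support <= 100):
                    raise TreeError(f"support {node.support!r} outside [0, 100]")
        if not seen:
            raise TreeError("tree has no leaves")

    # ------------------------------------------------------------------
    # traversal
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())

    def internal_nodes(self, exclude_root: bool = False) -> list[Node]:
        out = [n for n in self.postorder() if not n.is_leaf]
        if exclude_root:
            out = [n for n in out if n is not self.root]
        return out

    def find_leaf(self, label: str) -> Optional[Node]:
        for n in self.leaves():
            if n.label == label:
                return n
        return None

    # ------------------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.length, node.support)
            for child in node.children:
                c.add_child(clone(child))
            return c

        return PhyloTree(clone(self.root), rooted=self.rooted)

    # ------------------------------------------------------------------
    # newick
    def to_newick(self, lengths: bool = True, supports: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lab = ""
                if supports and node.support is not None:
                    lab = _fmt_num(node.support)
                elif node.label:
                    lab = node.label
                s = f"({inner}){lab}"
            if lengths and node.length is not None:
                s += f":{_fmt_num(node.length)}"
            return s

        return fmt(self.root) + ";"

    def __str__(self) -> str:
        return self.to_newick()

    # ------------------------------------------------------------------
    # surgery
    def suppress_unifurcations(self) -> None:
        """Collapse nodes with exactly one child, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node is self.root:
                    child.parent = None
                    # absorb the dangling root branch length into the child
                    if node.length is not None:
                        child.length = (child.length or 0.0) + node.length
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    parent.children[idx] = child
                    child.parent = parent
                    if node.length is not None or child.length is not None:
                        child.length = (node.length or 0.0) + (child.length or 0.0)
                    if child.support is None and not child.is_leaf:
                        child.support = node.support
                changed = True

    def prune_to(self, keep: Iterable[str]) -> "PhyloTree":
        """Restrict to the given leaf labels (copy); collapse unifurcations."""
        keep = set(keep)
        missing = keep - self.leaf_labels()
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        t = self.copy()

        def prune(node: Node) -> Optional[Node]:
            if node.is_leaf:
                return node if node.label in keep else None
            kept = [c for c in (prune(ch) for ch in node.children) if c is not None]
            node.children = []
            for c in kept:
                node.add_child(c)
            return node if kept else None

        root = prune(t.root)
        if root is None:
            raise TreeError("no leaves left after pruning")
        t.root = root
        root.parent = None
        t.suppress_unifurcations()
        t.root.length = None
        return t

    def unrooted_copy(self) -> "PhyloTree":
        """Copy with any basal bifurcation collapsed into a trifurcation."""
        t = self.copy()
        while len(t.root.children) == 2 and not all(c.is_leaf for c in t.root.children):
            # merge the root into one internal child
            a, b = t.root.children
            keepc = a if not a.is_leaf else b
            other = b if keepc is a else a
            t.root.children = []
            for ch in list(keepc.children):
                keepc.remove_child(ch)
                t.root.add_child(ch)
            t.root.add_child(other)
            if keepc.length is not None or other.length is not None:
                other.length = (other.length or 0.0) + (keepc.length or 0.0)
            if other.support is None and not other.is_leaf:
                other.support = keepc.support
        t.rooted = False
        return t


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


# ----------------------------------------------------------------------
# Bipartitions


@dataclass(frozen=True)
class Bipartition:
    """A split of a taxon set induced by an internal edge.

    Canonical orientation: ``side_a`` is the side *not* containing the
    lexicographically smallest taxon of the full taxon set, which makes
    equal splits compare and hash equal.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    @staticmethod
    def make(side: Iterable[str], taxon_set: Iterable[str]) -> "Bipartition":
        side = frozenset(side)
        taxa = frozenset(taxon_set)
        other = taxa - side
        if not side or not other:
            raise TreeError("bipartition sides must both be non-empty")
        if side & other:
            raise TreeError("bipartition sides overlap")
        smallest = min(taxa)
        if smallest in side:
            side, other = other, side
        return Bipartition(side, other)

    @property
    def taxon_set(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    def restrict(self, taxa: Iterable[str]) -> Optional["Bipartition"]:
        """Restriction to a taxon subset; None when it collapses (trivial)."""
        taxa = frozenset(taxa)
        a = self.side_a & taxa
        b = self.side_b & taxa
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition.make(a, a | b)

    def conflicts_with(self, other: "Bipartition") -> bool:
        """True when the two splits cannot coexist in one tree.

        Evaluated on the shared taxon set: incompatible iff all four
        pairwise side intersections are non-empty.
        """
        common = self.taxon_set & other.taxon_set
        r1 = self.restrict(common)
        r2 = other.restrict(common)
        if r1 is None or r2 is None:
            return False
        return all(
            r1_side & r2_side
            for r1_side in (r1.side_a, r1.side_b)
            for r2_side in (r2.side_a, r2.side_b)
        )

    def is_compatible_with(self, other: "Bipartition") -> bool:
        return not self.conflicts_with(other)

    def sort_key(self):
        return (tuple(sorted(self.side_a)), tuple(sorted(self.side_b)))

    def __str__(self) -> str:
        return "{}|{}".format(",".join(sorted(self.side_a)), ",".join(sorted(self.side_b)))


# ----------------------------------------------------------------------
# Parsing


def parse_newick(text: str) -> PhyloTree:
    """Parse one newick statement into a :class:`PhyloTree`.

    Internal node labels that parse as numbers in [0, 100] are read as
    bootstrap supports; other labels are kept as internal-node names.
    """
    if not text or not text.strip():
        raise TreeError("empty newick input")
    if not text.strip().endswith(";"):
        raise TreeError("newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
        else:
            node = Node(length=dnode.edge.length)
            raw = dnode.label
            if raw is not None:
                try:
                    val = float(raw)
                except ValueError:
                    node.label = raw
                else:
                    if 0 <= val <= 100:
                        node.support = val
                    else:
                        node.label = raw
            for child in dnode.child_nodes():
                node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None  # a root branch has no meaning here
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


# ----------------------------------------------------------------------
# Rooting


def root_ranked(tree: PhyloTree, outgroups: Sequence[str]) -> PhyloTree:
    """Root on the first-ranked outgroup present in the tree.

    Later-ranked labels are consulted only when every earlier one is
    missing, mirroring ranked rooting so that trees missing an outgroup
    gene still root consistently.  The returned tree has a binary root
    with the chosen outgroup on one side; the outgroup's branch length is
    split evenly across the new root edge.
    """
    present = tree.leaf_labels()
    chosen = next((o for o in outgroups if o in present), None)
    if chosen is None:
        raise TreeError("no outgroup found")
    t = tree.unrooted_copy()
    leaf = t.find_leaf(chosen)
    if leaf.parent is t.root and len(t.root.children) == 2:
        t.rooted = True
        return t

    # Re-hang the tree from the outgroup's edge.  Walk from the old
    # attachment point to the old root, reversing parent/child links;
    # supports and lengths stay with their original edges.
    new_root = Node()
    old_parent = leaf.parent
    old_parent.remove_child(leaf)
    half = None if leaf.length is None else leaf.length / 2.0
    leaf.length = half
    new_root.add_child(leaf)

    # reverse the path old_parent -> ... -> old root
    path = [old_parent]
    while path[-1].parent is not None:
        path.append(path[-1].parent)
    # detach path links
    for i in range(1, len(path)):
        path[i].remove_child(path[i - 1])

    new_root.add_child(path[0])
    # edge data of reversed edges: node i's edge (towards old root) becomes
    # the edge of node i+1 in the new orientation
    edge_data = [(n.length, n.support) for n in path]
    path[0].length, path[0].support = half, None
    for i, node in enumerate(path[:-1]):
        nxt = path[i + 1]
        node.add_child(nxt)
        nxt.length, nxt.support = edge_data[i]
    out = PhyloTree(new_root, rooted=True)
    out.suppress_unifurcations()
    out.rooted = True
    return out


# ----------------------------------------------------------------------
# Bipartition extraction / RF


def _edge_splits(tree: PhyloTree, min_support: Optional[float] = None):
    """Yield (node, Bipartition) for every qualifying internal edge, postorder."""
    taxa = tree.leaf_labels()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.label])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is tree.root or node.is_leaf:
            continue
        clade = below[id(node)]
        if len(clade) < 2 or len(taxa - clade) < 2:
            continue
        if min_support is not None and (node.support is None or node.support < min_support):
            continue
        yield node, Bipartition.make(clade, taxa)


def extract_bipartitions(
    tree: PhyloTree, min_support: Optional[float] = None
) -> set[Bipartition]:
    """Non-trivial splits of the tree, optionally support-filtered.

    Each split's taxon set is the full leaf set.  When ``min_support`` is
    given, edges whose support is missing or below the cutoff contribute
    nothing.  Polytomies simply contribute fewer splits.
    """
    if len(tree.leaf_labels()) < 4:
        raise TreeError("need >= 4 leaves to extract non-trivial bipartitions")
    return {bp for _, bp in _edge_splits(tree, min_support)}


def restricted_splits(
    tree: PhyloTree,
    taxa: Iterable[str],
    min_support: Optional[float] = None,
) -> list[Bipartition]:
    """Edge-induced splits restricted to a taxon subset, postorder, deduped.

    An edge qualifies on its own support; restriction happens afterwards,
    so a restricted split is "supported" if any original edge inducing it
    qualifies.  Used by conflict classification and RF on pruned trees.
    """
    taxa = frozenset(taxa)
    out: list[Bipartition] = []
    seen: set[Bipartition] = set()
    for _, bp in _edge_splits(tree, min_support):
        r = bp.restrict(taxa)
        if r is not None and r not in seen:
            seen.add(r)
            out.append(r)
    return out


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson–Foulds distance on the shared-leaf restriction.

    Both trees are restricted to their common leaves; the distance is the
    size of the symmetric difference of their non-trivial split sets.
    """
    shared = t1.leaf_labels() & t2.leaf_labels()
    if len(shared) < 4:
        raise TreeError("insufficient overlap: fewer than 4 shared leaves")
    s1 = set(restricted_splits(t1, shared))
    s2 = set(restricted_splits(t2, shared))
    return len(s1 ^ s2)


# ----------------------------------------------------------------------
# Summary statistics


@dataclass
class TreeStats:
    n_leaves: int
    tree_length: float
    root_to_tip_variance: float


def tree_stats(tree: PhyloTree) -> TreeStats:
    """Leaf count, total branch length, and root-to-tip path variance.

    The variance uses the sample (n-1) divisor over all root-to-leaf path
    lengths.  Every non-root node must carry a branch length.
    """
    missing = [
        n.label or "internal node"
        for n in tree.postorder()
        if n is not tree.root and n.length is None
    ]
    if missing:
        raise TreeError(f"missing branch lengths on: {missing}")
    total = sum(n.length for n in tree.postorder() if n is not tree.root)
    depths = []

    def walk(node: Node, depth: float) -> None:
        if node.is_leaf:
            depths.append(depth)
        for c in node.children:
            walk(c, depth + c.length)

    walk(tree.root, 0.0)
    n = len(depths)
    mean = sum(depths) / n
    var = sum((d - mean) ** 2 for d in depths) / (n - 1) if n > 1 else 0.0
    return TreeStats(n_leaves=n, tree_length=float(total), root_to_tip_variance=float(var))
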